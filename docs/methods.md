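# Methods

`tmequant` quantifies the spatial organisation of immune cells in tumor
tissue from multi-channel fluorescence immunohistochemistry, measures tumor
vessel volume from 3D MR angiography, and summarises survival experiments.
This note records the models and procedures implemented, the conventions and
defaults chosen where the underlying measurement protocol leaves them open,
and what the synthetic-data generator does and does not emulate.

## Coordinate and unit conventions

Pixels are addressed `(row, col)`, 0-based, with pixel centers at integer
coordinates; pixel `(i, j)` covers the half-open square
`[i-0.5, i+0.5) × [j-0.5, j+0.5)`. The *containing pixel* of a continuous
coordinate `x` is `floor(x + 0.5)` (round-half-up); the same rule decides
both the distance zero-rule and a centroid's grid membership, so there is a
single convention to audit. Physical distances are
`d_um = d_px / pixel_scale` with `pixel_scale` in px/µm (default 1.98,
typical of 10× widefield acquisition). MR volumes use isotropic voxels
(default 50 µm edge), so one voxel is `(0.05 mm)³ = 1.25e-4 mm³`.

Images are loaded without any intensity rescaling. The analysis assumes
constant-exposure acquisition without saturation, so raw intensities are
comparable across fields; any normalisation must be an explicit downstream
step. QC flags (saturation, near-empty tissue, strong illumination
gradients) are advisory and never silently drop data.

## Cell and structure segmentation

Marker-positive cells are detected by binarizing one channel at an intensity
threshold (strictly `>`), labelling 8-connected components, and filtering by
area and morphology. Centroids are unweighted means of member-pixel
coordinates. No splitting of touching cells is attempted — there is no
principled splitting rule without a nuclear counterstain model, and the
hard-core generator (below) makes contact rare in the tested regime.

The threshold is estimated from a *no-primary-antibody control* section as
`mean + k·SD` of the control channel (default `k = 3`), which makes the
procedure reproducible while still allowing a manual override per study.
With Gaussian background noise, `k = 3` passes ≈0.13 % of background pixels,
which the minimum-area filter (default 5 px²) then removes as isolated
speckle.

Morphology defaults: solidity ≥ 0.5 and eccentricity ≤ 0.99. An ideal disc
has solidity ≈ 0.9, but a ~50 px² component with a noise-ragged boundary
routinely measures 0.6–0.75, so 0.5 keeps genuine small cells while still
rejecting thin fibres and line-like debris. Area bounds default to
5–5000 px² and all four bounds are configurable; the same parameter set is
meant to be applied to every field of a study.

Structure area (e.g. αSMA⁺ stroma) is a plain intensity threshold; its area
fraction is the exact positive-pixel count over the image size. Fields are
split into structure-rich vs structure-poor halves about the *mean* area
fraction across fields, ties going to poor.

## Nearest-structure distances

For each cell, the Euclidean distance from its (continuous) centroid to the
nearest structure-positive *pixel center*, in µm. A centroid whose
containing pixel is itself positive scores exactly 0 — cells inside the
structure are recorded at zero rather than excluded. Distances are computed
with a k-d tree over the positive pixels, which is exact (not a grid-based
approximation); the test suite checks it against an exhaustive
cell-by-pixel scan to 1e-9 µm. Distances are conventionally binned at
`[0, 20) µm` and `[20 µm, ∞)`; the second fraction is the "far from stroma"
summary. An empty structure mask makes the distance undefined (an error);
an empty cell set yields an empty, explicitly flagged result.

## Grid-occupancy heterogeneity

The image is tiled into square grids of side 100 px (default); partial grids
at the right/bottom edges are included, so a H×W image has
`ceil(H/side)·ceil(W/side)` grids. A grid is *positive* under one of three
modes:

* `centroid` (default) — contains at least one cell centroid;
* `pixel_fraction` — at least 50 % of its pixels are structure-positive
  (partial grids use their actual pixel count);
* `either` — the union of both criteria.

More positive grids at equal cell count means a more homogeneous spatial
distribution. The default is the centroid criterion because occupancy of
the *cell* marker is the quantity of scientific interest; the two other
modes are provided because the combination of criteria used in comparable
published analyses is ambiguous, and the choice is recorded in the output.

## Vessel volumetry

Contrast-enhanced vessels are extracted by a relative 50 % threshold:
`v_min + 0.5·(v_max − v_min)` over the volume (an ITK-SNAP-style range
threshold). With percentile clipping off (the default) this is invariant to
affine intensity rescaling; clipping percentiles are offered for volumes
with hot outlier voxels and are recorded in the output. Whether "50 %"
should be of the max, of the range, or of a reference tissue cannot be
pinned down from typical methods descriptions; the range convention was
chosen and is reported alongside the threshold value actually applied.
Vessel volume is the positive-voxel count times the voxel volume — no
minimum-component filter by default (one can be applied upstream). At 50 µm
voxels this measurement includes arterioles/venules and excludes
capillaries; that is an acquisition limit, not a software rule. Maximum
intensity projections are per-pixel maxima along one axis.

## Survival statistics

Kaplan–Meier product-limit curves per group; at each distinct event time
`S ← S·(1 − d_t/n_t)`. Median survival is the smallest `t` with
`S(t) ≤ 0.5` (the left edge when `S` sits exactly at 0.5 over an interval),
undefined when the curve never reaches 0.5. Subjects alive at the study end
are censored there for the curve and counted as survivors for the *cure
rate* = `round(100·survivors/n)` (half-up). The median-survival increase is
reported as the next whole percent (ceiling): KM medians are day-rounded
step values, so the printed ratio is a lower bound on the true increase —
e.g. 30 vs 22 days reports 37 %, and 73.5 vs 55 days reports 34 %.

The two-group log-rank test sums observed-minus-expected events with
hypergeometric variance and refers `(O−E)²/V` to χ²(1). A group with zero
observed events reports the test as undefined rather than a p-value.
Multiplicity is handled by Holm step-down adjustments in Bonferroni
(`p·(m−i+1)`) and Šidák (`1−(1−p)^(m−i+1)`) flavours with enforced
monotonicity. One-way ANOVA is the classical between/within mean-square
ratio; the fully degenerate case (all values equal) reports `F = 0, p = 1`.

Closed-form quantifications: bead-corrected absolute counts
(`viable × total_beads / counted_beads`, unrounded), per-gram densities, and
ΔΔCt relative expression `2^(−ΔΔCt)` with amplification efficiency fixed at
2 (a reference gene such as β-actin normalises within sample, a calibrator
sample across groups).

## Synthetic data: what it emulates, and what it does not

**Fields.** Default: 600×600 px at 1.98 px/µm (~303 µm side), a 3×3 lattice
of 6-px-wide ribbons as the stromal (αSMA-like) structure, 100 cells
rendered as Gaussian blobs (σ = 4 px ≈ 2 µm, amplitude 50) on background 20
with additive Gaussian noise SD 10 — signal-to-noise ratio 5. Placement
processes: `uniform`; `excluded` (rejection-sampled ≥ 20 µm from structure,
mimicking stromal exclusion of T cells); `attracted` (thinning with density
`exp(−d/20 µm)`, mimicking perivascular accumulation). The lattice geometry
is deliberate: its lines traverse every 100-px analysis grid while leaving
~110-px pockets between them, so exclusion confines cells to isolated
pockets (few occupied grids, long distances) whereas attraction spreads
cells along lines through most grids — the qualitative signature the
spatial statistics are meant to detect. Cells receive a hard-core minimum
separation of `4σ` (≈ one 8 µm cell diameter) because cell bodies are
disjoint; setting it to 0 recovers an independent binomial process (used
when testing against closed-form occupancy expectations). Noise is additive
Gaussian with optional Poisson shot noise; clipped at zero. No PSF, no
autofluorescence texture, no folds or tears: passing recovery tests shows
the *algorithms* are correct at a realistic SNR, not that thresholds
transfer to any particular microscope.

**Phantoms.** Tubes are rendered by voxel-center membership (flat-ended
cylinders by default; spherocylinders optionally), with the analytic
`πr²L (+ 4/3πr³)` recorded alongside. A 64³ volume at 50 µm voxels with a
full-length axial cylinder gives voxelization errors of ~3.4 / 2.5 / 2.0 %
at radii 100 / 200 / 400 µm — within 10 % from 3 voxel radii up and
monotonically shrinking, which is the accuracy claim the volumetry tests
assert. No partial-volume blur, coil inhomogeneity, or flow artefacts are
simulated.

**Cohorts.** Exponential death times with a per-group median plus a cure
fraction; cured subjects and late deaths are censored at the study end
(default day 100, ~10 subjects/arm, matching small-animal survival study
scale). Real cohorts have staggered entry and loss to follow-up, which the
generator does not model.

All generators are deterministic: same spec and seed → bit-identical
output.

## Problem sizes in tests and the acceptance script

The automated checks use 512–600 px fields (0–100 cells), 64³ phantom
volumes, 100+ random oracle instances per statistic, 20 seeds for the
placement-regime comparison, and 2000 null replicates (n = 30+30) for
log-rank calibration. These sizes give comfortable statistical resolution
(e.g. the type-I check has Monte-Carlo SE ≈ 0.5 %) while keeping the whole
suite around a minute of CPU.

## Known limitations

* No watershed splitting: touching cells count as one object; density and
  occupancy are biased low in heavily clustered real tissue.
* The αSMA area threshold passes isolated background speckle at `k = 3`,
  which shortens measured distances on noisy fields (the regime ordering is
  robust to this; absolute distances are not). Raising `k` for the
  structure channel or filtering small mask components are the remedies.
* Relative-threshold volumetry is sensitive to a single extreme voxel when
  clipping is off.
* The nonparametric cure rate is a fraction, not a mixture-cure model; no
  Cox regression or Tukey HSD.
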