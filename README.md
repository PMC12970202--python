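# tmequant

Spatial quantification of tumor immune microenvironments from fluorescence
immunohistochemistry and MR angiography, plus the survival summaries used in
treatment studies.

Immune checkpoint therapies work only where T cells actually reach tumor
cells. Whether they do is a *spatial* question: are CD3⁺ T cells trapped at
αSMA⁺ stromal barriers (cancer-associated fibroblasts, perivascular cells)
or spread through the parenchyma? `tmequant` implements the measurement
pipeline for this question, for imaging scientists and tumor immunologists:

* **Segmentation** — threshold-based detection of marker-positive cells
  (intensity, size, morphology filters) and structure area, with thresholds
  estimated reproducibly from no-primary-antibody controls as
  `mean + k·SD`.
* **Distance to stroma** — for each cell centroid, the Euclidean distance
  to the nearest structure-positive pixel, `d_i = min_p ‖x_i − p‖ / s`
  (s = pixels/µm), with the fraction of cells beyond 20 µm as the exclusion
  summary.
* **Grid occupancy** — the image is tiled into 100-px squares and the
  number of grids containing at least one cell is counted; at equal cell
  number, more occupied grids = a more homogeneous infiltrate.
* **Vessel volumetry** — 3D MR angiography binarized at a relative 50 %
  intensity threshold; vessel volume = positive voxels × (voxel edge)³.
* **Survival statistics** — Kaplan–Meier `S(t) = Π (1 − d_t/n_t)`, median
  survival and its percent increase, cure rates, the two-group log-rank
  test, Holm–Bonferroni / Holm–Šídák step-down adjustments, one-way ANOVA,
  bead-corrected absolute counts and ΔΔCt (`2^−ΔΔCt`) expression.
* **Synthetic data** — ground-truth generators (blob cells under uniform /
  stroma-excluded / stroma-attracted placement around ribbon structures,
  tubular phantoms of known analytic volume, censored exponential cohorts
  with cure fractions) so that every stage is testable without microscope
  or scanner data.

See `docs/methods.md` for conventions, defaults, and limitations.

## Worked example

Generate a field whose cells are excluded from the stroma by ≥ 20 µm, then
recover that phenotype with the analysis stack:

```python
from tmequant import (FieldSpec, SegmentationParams, estimate_threshold,
                      generate_field, generate_control_field, segment_cells,
                      segment_area, nearest_structure_distances,
                      grid_occupancy, cell_density)

spec = FieldSpec(seed=11, placement="excluded")
field, truth_cells, truth_mask = generate_field(spec)

control = generate_control_field(FieldSpec(seed=99))          # no-primary control
thr_cell = estimate_threshold(control, "CD3")                 # mean + 3 SD
thr_stroma = estimate_threshold(control, "aSMA", k=5.0)       # stricter for area

cells = segment_cells(field, "CD3",
                      SegmentationParams(intensity_threshold=thr_cell))
stroma = segment_area(field, "aSMA", thr_stroma)
dist = nearest_structure_distances(cells, stroma, field.pixel_scale)
occ = grid_occupancy(cells, None, field.shape, grid_side_px=100,
                     mode="centroid")

print(f"cells detected: {len(cells)} (ground truth: {len(truth_cells)})")
print(f"mean distance to stroma: {dist.mean_um:.1f} um")
print(f"fraction of cells >20 um from stroma: {dist.bin_fractions[1]:.2f}")
print(f"grid occupancy: {occ.n_positive}/{occ.n_grids} grids occupied")
print(f"density: {cell_density(cells, field.shape, field.pixel_scale):.0f} cells/mm^2")
```

Output:

```
cells detected: 104 (ground truth: 100)
mean distance to stroma: 31.9 um
fraction of cells >20 um from stroma: 1.00
grid occupancy: 25/36 grids occupied
density: 1133 cells/mm^2
```

All 100 true cells are found (plus a few noise-split detections), every
cell is beyond the 20 µm exclusion radius the generator enforced, and the
cells occupy 25 of 36 grids — fewer than an `attracted` placement at the
same cell count and seed gives (32/36), which is exactly the heterogeneity
contrast the grid statistic measures.

The same operations are available from the shell:

```sh
tmequant simulate --kind field --placement excluded --seed 11 --out sim/
tmequant segment --image sim/field.tif --channel CD3 --threshold 49.5 --out cells.csv
tmequant distances --cells cells.csv --mask sim/truth_mask.npy --pixel-scale 1.98
tmequant run --config pipeline.yaml
```

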