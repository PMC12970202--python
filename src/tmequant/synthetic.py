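"""Ground-truth-known synthetic inputs for every pipeline stage.

Three generators emulate the statistical structure of the real inputs:

* **Fluorescence fields** — a cell channel of isotropic Gaussian blobs placed
  by a uniform, structure-excluded, or structure-attracted point process
  around ribbon-like stromal structures (an anti-aliased line lattice playing
  the role of an aSMA+ CAF network), plus additive Gaussian noise on a
  constant background.  Generated cells obey a hard-core minimum separation
  (cells are disjoint bodies), which can be switched off to obtain a pure
  binomial point process.
* **Angiography phantoms** — tubular vessels of known radius rendered into a
  3D volume by voxel-center membership, with the analytic cylinder volume
  recorded alongside.
* **Survival cohorts** — censored exponential death times with a cure
  fraction; cured subjects are censored at the end-of-study day.

All generators are deterministic: the same spec and seed give bit-identical
artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import AngioVolume, FluorescenceField
from .segmentation import Cell, CellSet, RegionMask
from .survival import SurvivalCohort

__all__ = [
    "Ribbon",
    "FieldSpec",
    "Tube",
    "PhantomSpec",
    "GroupSpec",
    "CohortSpec",
    "default_ribbons",
    "generate_field",
    "generate_control_field",
    "generate_phantom",
    "generate_cohort",
]

CELL_CHANNEL = "CD3"
STRUCTURE_CHANNEL = "aSMA"


# ---------------------------------------------------------------------------
# fluorescence fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ribbon:
    """A straight stromal ribbon segment, endpoints in (row, col) pixels."""

    start_rc: tuple[float, float]
    end_rc: tuple[float, float]
    width_px: float = 6.0


@dataclass(frozen=True)
class FieldSpec:
    """Recipe for one synthetic two-channel field.

    Defaults describe a 600x600 px field at 1.98 px/um (~303 um side) with a
    3x3 stromal line lattice and 100 cells at signal-to-noise ratio
    ``blob_amplitude / noise_sd = 5``.  ``min_separation_px=None`` means a
    hard-core separation of ``4 * blob_sigma_px`` (about one cell diameter);
    pass 0 for an independent (binomial) point process.
    """

    shape: tuple[int, int] = (600, 600)
    pixel_scale: float = 1.98
    n_cells: int = 100
    placement: str = "uniform"  # uniform | excluded | attracted
    exclusion_radius_um: float = 20.0
    attraction_scale_um: float = 20.0
    structure: tuple[Ribbon, ...] | None = None  # None -> default lattice
    blob_sigma_px: float = 4.0
    blob_amplitude: float = 50.0
    noise_sd: float = 10.0
    background: float = 20.0
    min_separation_px: float | None = None
    poisson_noise: bool = False
    seed: int = 0
    field_id: str = ""
    group_label: str = ""


def default_ribbons(shape: tuple[int, int]) -> tuple[Ribbon, ...]:
    """A 3x3 lattice of crossing ribbons spanning the field.

    The lattice traverses every row and column of 100-px analysis grids while
    leaving pockets between the lines that are more than ~20 um from any
    structure, so excluded and attracted placements produce visibly different
    occupancy patterns.
    """
    H, W = shape
    ribbons = []
    for f in (50 / 600, 250 / 600, 450 / 600):
        r = f * H
        c = f * W
        ribbons.append(Ribbon((r, 0.0), (r, W - 1.0)))
        ribbons.append(Ribbon((0.0, c), (H - 1.0, c)))
    return tuple(ribbons)


def _segment_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance from (n,2) points to the segment p0-p1 (capsule metric)."""
    v = p1 - p0
    L2 = float(v @ v)
    if L2 == 0:
        return np.linalg.norm(points - p0, axis=-1)
    t = np.clip((points - p0) @ v / L2, 0.0, 1.0)
    proj = p0 + t[..., None] * v
    return np.linalg.norm(points - proj, axis=-1)


def _render_structure(shape: tuple[int, int], ribbons: Sequence[Ribbon]):
    """Binary ribbon mask and an anti-aliased [0,1] intensity profile."""
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    profile = np.zeros(shape, dtype=float)
    if not ribbons:
        return mask, profile
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    pts = np.stack([rr, cc], axis=-1)
    dmin = np.full(shape, np.inf)
    half_w = np.zeros(shape)
    for rb in ribbons:
        d = _segment_distance(pts, np.asarray(rb.start_rc, float),
                              np.asarray(rb.end_rc, float))
        closer = d < dmin
        dmin = np.where(closer, d, dmin)
        half_w = np.where(closer, rb.width_px / 2.0, half_w)
    mask = dmin <= half_w
    # soft 1-px anti-aliased edge for the rendered intensity
    profile = np.clip(half_w + 0.5 - dmin, 0.0, 1.0)
    return mask, profile


def _structure_distance_um(points_rc: np.ndarray, mask: np.ndarray,
                           tree: cKDTree, pixel_scale: float) -> np.ndarray:
    """Same nearest-positive-pixel metric the analysis uses (containment -> 0)."""
    d_px, _ = tree.query(points_rc)
    rows = np.clip(np.floor(points_rc[:, 0] + 0.5).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.floor(points_rc[:, 1] + 0.5).astype(int), 0, mask.shape[1] - 1)
    d_px = np.where(mask[rows, cols], 0.0, d_px)
    return d_px / pixel_scale


def _sample_centroids(spec: FieldSpec, mask: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    H, W = spec.shape
    sep = (4.0 * spec.blob_sigma_px if spec.min_separation_px is None
           else spec.min_separation_px)
    if spec.placement not in ("uniform", "excluded", "attracted"):
        raise ValueError(f"unknown placement {spec.placement!r}")
    if spec.placement != "uniform" and not mask.any():
        raise ValueError(f"placement {spec.placement!r} needs a non-empty structure")
    tree = cKDTree(np.argwhere(mask)) if mask.any() else None

    accepted: list[np.ndarray] = []
    attempts = 0
    max_attempts = 20000 + 5000 * spec.n_cells
    batch = 256
    while len(accepted) < spec.n_cells:
        if attempts >= max_attempts:
            raise ValueError(
                "infeasible placement: could not place "
                f"{spec.n_cells} cells under {spec.placement!r} constraints"
            )
        cand = np.column_stack([rng.uniform(0, H - 1, size=batch),
                                rng.uniform(0, W - 1, size=batch)])
        u = rng.random(batch)  # drawn unconditionally to keep the stream aligned
        attempts += batch
        if tree is not None and spec.placement != "uniform":
            d_um = _structure_distance_um(cand, mask, tree, spec.pixel_scale)
            if spec.placement == "excluded":
                keep = d_um >= spec.exclusion_radius_um
            else:  # attracted: thinning with density exp(-d / scale)
                keep = u < np.exp(-d_um / spec.attraction_scale_um)
            cand = cand[keep]
        for pt in cand:
            if len(accepted) >= spec.n_cells:
                break
            if sep > 0 and accepted:
                dmin = np.min(np.linalg.norm(np.asarray(accepted) - pt, axis=1))
                if dmin < sep:
                    continue
            accepted.append(pt)
    return np.asarray(accepted) if accepted else np.empty((0, 2))


def generate_field(spec: FieldSpec):
    """Render one synthetic field with its ground truth.

    Returns ``(FluorescenceField, CellSet, RegionMask)`` where the cell set
    holds the true (continuous) centroids and the mask is the true binary
    structure.  Deterministic for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    ribbons = default_ribbons(spec.shape) if spec.structure is None else tuple(spec.structure)
    mask, profile = _render_structure(spec.shape, ribbons)
    centroids = (_sample_centroids(spec, mask, rng) if spec.n_cells > 0
                 else np.empty((0, 2)))

    H, W = spec.shape
    cell_img = np.zeros(spec.shape, dtype=float)
    s = spec.blob_sigma_px
    win = int(math.ceil(4 * s))
    for r0, c0 in centroids:
        r_lo, r_hi = max(0, int(r0) - win), min(H, int(r0) + win + 1)
        c_lo, c_hi = max(0, int(c0) - win), min(W, int(c0) + win + 1)
        rr = np.arange(r_lo, r_hi, dtype=float)[:, None]
        cc = np.arange(c_lo, c_hi, dtype=float)[None, :]
        cell_img[r_lo:r_hi, c_lo:c_hi] += spec.blob_amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s * s))

    struct_img = spec.blob_amplitude * profile

    channels = {}
    for name, signal in ((CELL_CHANNEL, cell_img), (STRUCTURE_CHANNEL, struct_img)):
        img = spec.background + signal
        if spec.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        channels[name] = np.clip(img, 0.0, None)

    fld = FluorescenceField(channels=channels, pixel_scale=spec.pixel_scale,
                            field_id=spec.field_id or f"synthetic_{spec.seed}",
                            group_label=spec.group_label)
    truth_cells = CellSet(
        channel=CELL_CHANNEL,
        cells=[Cell(label_id=i + 1, centroid_rc=(float(r), float(c)),
                    area_px=float(2 * math.pi * s * s))
               for i, (r, c) in enumerate(centroids)],
        source_field_id=fld.field_id,
    )
    truth_mask = RegionMask(channel=STRUCTURE_CHANNEL, mask=mask,
                            source_field_id=fld.field_id)
    return fld, truth_cells, truth_mask


def generate_control_field(spec: FieldSpec) -> FluorescenceField:
    """A secondary-antibody-only control: background plus noise, no signal.

    Used to estimate intensity thresholds exactly as for real no-primary
    control sections.
    """
    ctrl = replace(spec, n_cells=0, structure=(),
                   field_id=(spec.field_id or f"synthetic_{spec.seed}") + "_control")
    fld, _, _ = generate_field(ctrl)
    return fld


# ---------------------------------------------------------------------------
# angiography phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tube:
    """A tubular vessel: endpoints in physical um (z, y, x order), radius um.

    ``capped=False`` renders a flat-ended cylinder (analytic volume pi r^2 L);
    ``capped=True`` a spherocylinder (adds 4/3 pi r^3).
    """

    start_um: tuple[float, float, float]
    end_um: tuple[float, float, float]
    radius_um: float
    intensity: float = 100.0
    capped: bool = False


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = 50.0
    tubes: tuple[Tube, ...] = ()
    background_intensity: float = 0.0
    noise_sd: float = 2.0
    seed: int = 0
    volume_id: str = ""


def _tube_extent(tube: Tube) -> tuple[np.ndarray, np.ndarray]:
    p0 = np.asarray(tube.start_um, float)
    p1 = np.asarray(tube.end_um, float)
    v = p1 - p0
    L = np.linalg.norm(v)
    if tube.capped or L == 0:
        pad = np.full(3, tube.radius_um)
    else:
        vh = v / L
        pad = tube.radius_um * np.sqrt(np.clip(1.0 - vh**2, 0.0, 1.0))
    return np.minimum(p0, p1) - pad, np.maximum(p0, p1) + pad


def generate_phantom(spec: PhantomSpec):
    """Render tubular vessels into a 3D volume; return it with analytic volume.

    A voxel is vessel-positive when its center lies within a tube's radius of
    the tube axis (flat-ended: the axial projection must also fall inside the
    segment).  The analytic volume (mm^3) of all tubes is returned alongside;
    overlap between tubes is not deduplicated in the analytic sum, so disjoint
    tubes should be used when the sum is compared to voxel counts.
    """
    rng = np.random.default_rng(spec.seed)
    vox = spec.voxel_size_um
    lo_bound = -0.5 * vox
    hi_bound = (np.asarray(spec.shape) - 0.5) * vox
    tol = 1e-6 * vox
    analytic_mm3 = 0.0
    inside = np.zeros(spec.shape, dtype=bool)
    intensity = np.full(spec.shape, spec.background_intensity, dtype=float)

    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) * vox for n in spec.shape),
                             indexing="ij")
    centers = np.stack([zz, yy, xx], axis=-1)

    for tube in spec.tubes:
        lo, hi = _tube_extent(tube)
        if np.any(lo < lo_bound - tol) or np.any(hi > hi_bound + tol):
            raise ValueError(f"tube exits volume bounds: extent {lo}..{hi}")
        p0 = np.asarray(tube.start_um, float)
        p1 = np.asarray(tube.end_um, float)
        v = p1 - p0
        L = float(np.linalg.norm(v))
        if L == 0:
            raise ValueError("degenerate tube with coincident endpoints")
        vh = v / L
        rel = centers - p0
        t = rel @ vh
        radial2 = np.einsum("...i,...i", rel, rel) - t**2
        r2 = tube.radius_um**2
        if tube.capped:
            tc = np.clip(t, 0.0, L)
            closest = p0 + tc[..., None] * vh
            d2 = np.einsum("...i,...i", centers - closest, centers - closest)
            member = d2 <= r2
            analytic_mm3 += (math.pi * r2 * L + 4.0 / 3.0 * math.pi * tube.radius_um**3) * 1e-9
        else:
            member = (t >= 0) & (t <= L) & (radial2 <= r2)
            analytic_mm3 += math.pi * r2 * L * 1e-9
        inside |= member
        intensity[member] = np.maximum(intensity[member], tube.intensity)

    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = AngioVolume(intensity=intensity, voxel_size_um=vox,
                      volume_id=spec.volume_id or f"phantom_{spec.seed}")
    return vol, analytic_mm3


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One treatment arm: exponential median survival plus a cure fraction."""

    name: str
    median_days: float
    cure_fraction: float = 0.0

    def __post_init__(self):
        if self.median_days <= 0:
            raise ValueError("median_days must be positive")
        if not (0 <= self.cure_fraction < 1):
            raise ValueError("cure_fraction must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort recipe; defaults mirror a small-animal survival study
    (about ten subjects per arm, study end at day 100)."""

    groups: tuple[GroupSpec, ...]
    n_per_group: int = 10
    end_of_study_day: float = 100.0
    seed: int = 0


def generate_cohort(spec: CohortSpec) -> SurvivalCohort:
    """Simulate per-subject survival records.

    Each subject is cured with its group's probability (censored at the
    end-of-study day); otherwise its death time is exponential with the
    group's median, censored at the study end if it exceeds it.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for grp in spec.groups:
        scale = grp.median_days / math.log(2)
        cured = rng.random(spec.n_per_group) < grp.cure_fraction
        t_death = rng.exponential(scale, size=spec.n_per_group)
        for i in range(spec.n_per_group):
            if cured[i] or t_death[i] > spec.end_of_study_day:
                t, ev = spec.end_of_study_day, 0
            else:
                t, ev = float(t_death[i]), 1
            rows.append({"subject_id": f"{grp.name}_{i:03d}", "group": grp.name,
                         "time_days": t, "event": ev})
    return SurvivalCohort(pd.DataFrame(rows))
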