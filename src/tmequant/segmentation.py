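"""Marker-positive cell and structure-area segmentation.

Cells (e.g. CD3+ T cells) are detected from a single channel by intensity
binarization, 8-connected component labelling, and size/morphology filters;
structure area (e.g. aSMA+ stroma) by intensity thresholding alone.  The
intensity threshold is estimated reproducibly from no-primary-antibody control
sections as mean + k*SD of the control channel; the same parameters are meant
to be applied to every field of a study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .io import FluorescenceField

__all__ = [
    "SegmentationParams",
    "Cell",
    "CellSet",
    "RegionMask",
    "QCFlag",
    "estimate_threshold",
    "segment_cells",
    "segment_area",
    "qc_flags",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Intensity, size and morphology bounds for cell detection.

    Morphology bounds are permissive defaults (solidity >= 0.5, eccentricity
    <= 0.99) that reject thin fibres and line-like debris while keeping small
    cells whose pixelated, noise-ragged boundaries depress solidity well
    below the ~0.9 of an ideal disc; all are configurable.
    """

    intensity_threshold: float
    min_area_px: float = 5.0
    max_area_px: float = 5000.0
    min_solidity: float = 0.5
    max_eccentricity: float = 0.99

    def __post_init__(self):
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be >= 0")
        if not (0 < self.min_area_px <= self.max_area_px):
            raise ValueError("need 0 < min_area_px <= max_area_px")
        if not (0 < self.min_solidity <= 1):
            raise ValueError("min_solidity must be in (0, 1]")
        if not (0 <= self.max_eccentricity <= 1):
            raise ValueError("max_eccentricity must be in [0, 1]")


@dataclass(frozen=True)
class Cell:
    label_id: int
    centroid_rc: tuple[float, float]
    area_px: float


@dataclass
class CellSet:
    """Detected objects for one marker channel of one field."""

    channel: str
    cells: list[Cell]
    source_field_id: str = ""

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of (row, col) centroids; shape (0, 2) when empty."""
        if not self.cells:
            return np.empty((0, 2))
        return np.array([c.centroid_rc for c in self.cells], dtype=float)


@dataclass
class RegionMask:
    """Binary structure mask with its exact positive-area fraction."""

    channel: str
    mask: np.ndarray
    area_fraction: float = field(init=False)
    source_field_id: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        self.area_fraction = float(self.mask.sum()) / self.mask.size


@dataclass(frozen=True)
class QCFlag:
    field_id: str
    channel: str
    flag: str
    detail: str


def estimate_threshold(control_field: FluorescenceField, channel: str,
                       k: float = 3.0) -> float:
    """Threshold from a secondary-antibody-only (no-primary) control section.

    Returns ``mean + k * SD`` of the control channel intensities (sample SD;
    zero for constant controls, so a constant control returns its mean).
    Deterministic given the control image.
    """
    vals = control_field.channel(channel).astype(float).ravel()
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)) + k * sd


def segment_cells(field: FluorescenceField, channel: str,
                  params: SegmentationParams) -> CellSet:
    """Detect marker-positive cells in one channel.

    Pixels strictly above ``params.intensity_threshold`` are labelled with
    8-connectivity; components outside the area bounds or failing the
    solidity/eccentricity bounds are discarded.  Centroids are the unweighted
    mean of member-pixel (row, col) coordinates.  An all-negative image yields
    an empty :class:`CellSet`, not an error.  No splitting of touching cells
    is attempted.
    """
    img = field.channel(channel)
    binary = np.asarray(img, dtype=float) > params.intensity_threshold
    labels = measure.label(binary, connectivity=2)
    cells: list[Cell] = []
    for prop in measure.regionprops(labels):
        if not (params.min_area_px <= prop.area <= params.max_area_px):
            continue
        if prop.solidity < params.min_solidity:
            continue
        if prop.eccentricity > params.max_eccentricity:
            continue
        cells.append(Cell(label_id=int(prop.label),
                          centroid_rc=(float(prop.centroid[0]), float(prop.centroid[1])),
                          area_px=float(prop.area)))
    return CellSet(channel=channel, cells=cells, source_field_id=field.field_id)


def segment_area(field: FluorescenceField, channel: str,
                 intensity_threshold: float) -> RegionMask:
    """Binary structure mask: pixels strictly above the threshold."""
    img = field.channel(channel)
    mask = np.asarray(img, dtype=float) > intensity_threshold
    return RegionMask(channel=channel, mask=mask, source_field_id=field.field_id)


def qc_flags(field: FluorescenceField, near_empty_floor: float = 0.01,
             gradient_factor: float = 10.0) -> list[QCFlag]:
    """Advisory quality-control findings for a field.

    Flags per channel: ``saturation`` (any pixel at the dtype maximum, integer
    dtypes only), ``near_empty`` (foreground fraction below ``near_empty_floor``,
    foreground being pixels above 10% of the channel maximum), and
    ``illumination_gradient`` (ratio of the largest to smallest row or column
    median exceeds ``gradient_factor``).  Findings are advisory only.
    """
    flags: list[QCFlag] = []
    for name, arr in field.channels.items():
        vals = np.asarray(arr, dtype=float)
        if np.issubdtype(np.asarray(arr).dtype, np.integer):
            dmax = np.iinfo(np.asarray(arr).dtype).max
            n_sat = int((np.asarray(arr) == dmax).sum())
            if n_sat:
                flags.append(QCFlag(field.field_id, name, "saturation",
                                    f"{n_sat} pixels at dtype max {dmax}"))
        vmax = vals.max()
        fg = float((vals > 0.1 * vmax).mean()) if vmax > 0 else 0.0
        if fg < near_empty_floor:
            flags.append(QCFlag(field.field_id, name, "near_empty",
                                f"foreground fraction {fg:.4f} < {near_empty_floor}"))
        eps = 1e-12
        for axis, label in ((1, "row"), (0, "col")):
            med = np.median(vals, axis=axis)
            lo, hi = float(med.min()), float(med.max())
            if lo > eps and hi / lo > gradient_factor:
                flags.append(QCFlag(field.field_id, name, "illumination_gradient",
                                    f"{label} median range {lo:.3g}..{hi:.3g}"))
                break
    return flags
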