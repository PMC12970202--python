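"""Spatial statistics of cell distributions relative to stromal structure.

Two statistics drive the analysis:

* **Nearest-structure distance** — for each detected cell, the Euclidean
  distance from its centroid to the nearest structure-positive pixel center,
  in micrometres.  A centroid whose containing pixel is itself mask-positive
  is inside the structure and scores exactly 0.  Distances are conventionally
  binned at 20 um to report the fraction of cells far from the structure.
* **Grid occupancy** — the image is tiled into square grids (default side
  100 px) and the number of occupied grids counted; more occupied grids means
  a more homogeneous spatial distribution of the cells.  A grid can be scored
  by centroid presence, by mask pixel fraction (>= 50% positive), or by the
  union of both.

Also provided: areal cell density (cells per mm^2) and the partition of
fields into structure-rich vs structure-poor halves about the mean area
fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .segmentation import CellSet, RegionMask

__all__ = [
    "DistanceResult",
    "GridHeterogeneity",
    "RichPoorPartition",
    "nearest_structure_distances",
    "bin_distances",
    "grid_occupancy",
    "cell_density",
    "split_rich_poor",
]

DEFAULT_BIN_EDGES_UM = (0.0, 20.0)
DEFAULT_GRID_SIDE_PX = 100


@dataclass
class DistanceResult:
    """Per-cell nearest-structure distances (um) with binned summary."""

    per_cell_um: np.ndarray
    mean_um: float  # NaN when no cells (flagged by n_cells == 0)
    bin_edges_um: tuple[float, ...]
    bin_fractions: np.ndarray  # NaN-filled when no cells

    @property
    def n_cells(self) -> int:
        return int(self.per_cell_um.size)


@dataclass
class GridHeterogeneity:
    grid_side_px: int
    n_grids: int
    n_positive: int
    mode: str

    @property
    def occupancy_fraction(self) -> float:
        return self.n_positive / self.n_grids


@dataclass
class RichPoorPartition:
    rich: list
    poor: list
    cutoff: float


def nearest_structure_distances(
    cells: CellSet,
    mask: RegionMask,
    pixel_scale: float,
    bin_edges_um: Sequence[float] = DEFAULT_BIN_EDGES_UM,
) -> DistanceResult:
    """Distance from each cell centroid to the nearest structure-positive pixel.

    Distances are pixel-center to pixel-center Euclidean (centroids are not
    snapped to the grid), converted to um by dividing by ``pixel_scale``.
    A centroid whose containing pixel (round-half-up of each coordinate) is
    mask-positive scores exactly 0.  An empty mask makes the distance
    undefined and raises; an empty cell set returns an empty result with NaN
    mean and NaN bin fractions.
    """
    m = mask.mask
    pos = np.argwhere(m)
    if pos.shape[0] == 0:
        raise ValueError("structure mask has no positive pixels; distance undefined")
    cent = cells.centroids
    if cent.shape[0] == 0:
        nb = len(_normalize_edges(bin_edges_um)) - 1
        return DistanceResult(np.empty(0), float("nan"),
                              tuple(bin_edges_um), np.full(nb, np.nan))
    tree = cKDTree(pos)
    d_px, _ = tree.query(cent)
    # containment rule: centroid inside a positive pixel -> distance 0
    rows = np.clip(np.floor(cent[:, 0] + 0.5).astype(int), 0, m.shape[0] - 1)
    cols = np.clip(np.floor(cent[:, 1] + 0.5).astype(int), 0, m.shape[1] - 1)
    d_px = np.where(m[rows, cols], 0.0, d_px)
    d_um = d_px / pixel_scale
    fractions = bin_distances(d_um, bin_edges_um)
    return DistanceResult(d_um, float(d_um.mean()), tuple(bin_edges_um), fractions)


def _normalize_edges(edges_um: Sequence[float]) -> np.ndarray:
    edges = np.asarray(edges_um, dtype=float)
    if edges.size and not math.isinf(edges[-1]):
        edges = np.append(edges, np.inf)
    if edges.size < 2 or edges[0] != 0:
        raise ValueError("edges must start at 0 and define at least one bin")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be strictly increasing")
    return edges


def bin_distances(distances, edges_um: Sequence[float] = DEFAULT_BIN_EDGES_UM) -> np.ndarray:
    """Fraction of cells in each half-open bin ``[e_i, e_{i+1})``.

    The final bin is closed above at infinity, so with the default edges the
    second entry is the fraction of cells more than 20 um from the structure.
    """
    if isinstance(distances, DistanceResult):
        distances = distances.per_cell_um
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances to bin")
    edges = _normalize_edges(edges_um)
    idx = np.searchsorted(edges, d, side="right") - 1
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    return counts / d.size


def grid_occupancy(
    cells: CellSet | None,
    mask: RegionMask | None,
    field_shape: tuple[int, int],
    grid_side_px: int = DEFAULT_GRID_SIDE_PX,
    mode: str = "centroid",
) -> GridHeterogeneity:
    """Count occupied square grids as a spatial-heterogeneity statistic.

    The image is tiled into ``grid_side_px``-sided squares; partial grids at
    the right/bottom edges are included (so ``n_grids =
    ceil(H/side) * ceil(W/side)``).  A grid is positive when:

    * ``centroid`` mode — it contains at least one cell centroid (membership
      by the centroid's containing pixel);
    * ``pixel_fraction`` mode — at least 50% of its pixels are mask-positive
      (partial grids use their actual pixel count);
    * ``either`` mode — the union of both criteria.
    """
    if grid_side_px < 1:
        raise ValueError("grid_side_px must be >= 1")
    if mode not in ("centroid", "pixel_fraction", "either"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "centroid" and mask is None:
        raise ValueError(f"mode {mode!r} requires a structure mask")
    H, W = field_shape
    n_rows = math.ceil(H / grid_side_px)
    n_cols = math.ceil(W / grid_side_px)
    positive = np.zeros((n_rows, n_cols), dtype=bool)

    if mode in ("centroid", "either") and cells is not None and len(cells):
        cent = cells.centroids
        rows = np.clip(np.floor(cent[:, 0] + 0.5).astype(int), 0, H - 1)
        cols = np.clip(np.floor(cent[:, 1] + 0.5).astype(int), 0, W - 1)
        positive[rows // grid_side_px, cols // grid_side_px] = True

    if mode in ("pixel_fraction", "either"):
        m = mask.mask
        for gi in range(n_rows):
            for gj in range(n_cols):
                tile = m[gi * grid_side_px:(gi + 1) * grid_side_px,
                         gj * grid_side_px:(gj + 1) * grid_side_px]
                if tile.sum() >= 0.5 * tile.size:
                    positive[gi, gj] = True

    return GridHeterogeneity(grid_side_px=grid_side_px,
                             n_grids=n_rows * n_cols,
                             n_positive=int(positive.sum()),
                             mode=mode)


def cell_density(cells: CellSet, field_shape: tuple[int, int],
                 pixel_scale: float) -> float:
    """Areal cell density in cells per mm^2."""
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    H, W = field_shape
    if H * W == 0:
        raise ValueError("zero-area field")
    area_mm2 = (H * W) / pixel_scale**2 / 1e6
    return len(cells) / area_mm2


def split_rich_poor(masks) -> RichPoorPartition:
    """Partition fields into structure-rich and structure-poor halves.

    The cutoff is the mean positive-area fraction across fields; a field is
    *rich* when its fraction strictly exceeds the cutoff and *poor* otherwise
    (ties go to poor).  Accepts a sequence of :class:`RegionMask` (ids taken
    from ``source_field_id`` or position) or a mapping id -> area fraction.
    """
    if isinstance(masks, Mapping):
        items = list(masks.items())
    else:
        items = [(m.source_field_id or i, m.area_fraction)
                 for i, m in enumerate(masks)]
    if len(items) < 2:
        raise ValueError("need at least 2 fields to split")
    cutoff = float(np.mean([f for _, f in items]))
    rich = [i for i, f in items if f > cutoff]
    poor = [i for i, f in items if f <= cutoff]
    return RichPoorPartition(rich=rich, poor=poor, cutoff=cutoff)
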