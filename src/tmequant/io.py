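"""Image and table I/O plus the coordinate/unit conventions shared by all analyses.

Conventions (fixed across the package):

* Pixels are addressed ``(row, col)``, 0-based, with pixel *centers* at integer
  coordinates; pixel ``(i, j)`` covers ``[i-0.5, i+0.5) x [j-0.5, j+0.5)``.
* Physical distance conversion is ``distance_um = distance_px / pixel_scale``
  with ``pixel_scale`` in pixels per micrometre (default 1.98 px/um, typical of
  10x fluorescence acquisition).
* No intensity rescaling happens on load: images are assumed acquired at
  constant exposure without saturation, so raw intensities are comparable
  across fields and any normalization must be explicit downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceField",
    "AngioVolume",
    "read_field",
    "write_field",
    "read_volume",
    "write_volume",
    "write_results",
    "px_to_um",
    "um_to_px",
    "containing_pixel",
]

#: default pixel scale of the fluorescence micrographs, pixels per micrometre
DEFAULT_PIXEL_SCALE = 1.98
#: default MR angiography voxel edge, micrometres (isotropic)
DEFAULT_VOXEL_UM = 50.0


def px_to_um(distance_px, pixel_scale: float):
    """Convert pixel distances to micrometres (``d_um = d_px / pixel_scale``)."""
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    return np.asarray(distance_px, dtype=float) / pixel_scale


def um_to_px(distance_um, pixel_scale: float):
    """Convert micrometre distances to pixels."""
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    return np.asarray(distance_um, dtype=float) * pixel_scale


def containing_pixel(coord: float) -> int:
    """Index of the pixel whose cell contains a continuous coordinate.

    Pixel centers sit at integer coordinates, so the containing pixel of ``x``
    is ``floor(x + 0.5)`` (round-half-up).  This single rule is shared by the
    distance zero-rule and grid membership of centroids.
    """
    return int(np.floor(coord + 0.5))


@dataclass
class FluorescenceField:
    """A multi-channel 2D fluorescence micrograph with physical pixel scale.

    Parameters
    ----------
    channels
        Mapping channel label (e.g. ``"DAPI"``, ``"CD3"``, ``"aSMA"``) to a 2D
        intensity array in arbitrary units.  All channels must share one shape.
    pixel_scale
        Pixels per micrometre (> 0).
    field_id, group_label
        Free-text identifiers; ``group_label`` is the treatment group and is
        only joined to measurements at the reporting stage.
    """

    channels: Mapping[str, np.ndarray]
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    field_id: str = ""
    group_label: str = ""

    def __post_init__(self):
        if not self.channels:
            raise ValueError("field must have at least one channel")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2D, got shape {shape}")
        for name, arr in self.channels.items():
            vals = arr.astype(float, copy=False)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"channel {name!r} has non-finite intensities")
            if vals.min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in field {self.field_id!r}; "
                f"available: {sorted(self.channels)}"
            ) from None


@dataclass
class AngioVolume:
    """A 3D MR-angiography intensity volume with isotropic voxel size (um)."""

    intensity: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_UM
    volume_id: str = ""

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.intensity.ndim}")
        if min(self.intensity.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um / 1000.0) ** 3


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------

def read_field(
    path,
    channel_names: Sequence[str],
    pixel_scale: float = DEFAULT_PIXEL_SCALE,
    field_id: str | None = None,
    group_label: str = "",
) -> FluorescenceField:
    """Read a multi-page TIFF as a :class:`FluorescenceField`.

    TIFF pages map to channels in file order; names come from the caller, not
    from metadata.  Raw intensities are kept as stored (no rescaling).
    """
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected 2D pages, got array of ndim {stack.ndim}")
    if stack.shape[0] != len(channel_names):
        raise ValueError(
            f"channel-count mismatch: file has {stack.shape[0]} pages, "
            f"{len(channel_names)} names given"
        )
    channels = {name: stack[i] for i, name in enumerate(channel_names)}
    return FluorescenceField(
        channels=channels,
        pixel_scale=pixel_scale,
        field_id=field_id if field_id is not None else path.stem,
        group_label=group_label,
    )


def write_field(field: FluorescenceField, path) -> None:
    """Write a field as a multi-page TIFF, one page per channel in dict order."""
    import tifffile

    stack = np.stack(list(field.channels.values()))
    # one grayscale page per channel (never RGB-interpreted)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_volume(path, voxel_size_um: float = DEFAULT_VOXEL_UM,
                volume_id: str | None = None) -> AngioVolume:
    """Read a 3D volume from NIfTI (``.nii``/``.nii.gz``) or multi-page TIFF.

    If the container declares a voxel spacing that disagrees with
    ``voxel_size_um`` a warning is issued and the argument wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if voxel_size_um <= 0:
        raise ValueError("voxel_size_um must be positive")
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        declared_um = float(zooms[0]) * 1000.0  # NIfTI spacing stored in mm
        if declared_um > 0 and abs(declared_um - voxel_size_um) > 1e-6 * voxel_size_um:
            warnings.warn(
                f"container declares {declared_um:g} um spacing but "
                f"{voxel_size_um:g} um was requested; using the argument",
                stacklevel=2,
            )
    else:
        import tifffile

        data = tifffile.imread(str(path))
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
    return AngioVolume(
        intensity=data,
        voxel_size_um=voxel_size_um,
        volume_id=volume_id if volume_id is not None else path.stem,
    )


def write_volume(vol: AngioVolume, path) -> None:
    """Write a volume as NIfTI-1 with spacing recorded in mm."""
    import nibabel as nib

    mm = vol.voxel_size_um / 1000.0
    img = nib.Nifti1Image(np.asarray(vol.intensity), affine=np.diag([mm, mm, mm, 1.0]))
    img.header.set_zooms((mm, mm, mm))
    nib.save(img, str(path))


def write_results(records, path, format: str = "csv") -> None:
    """Write tabular results to CSV (RFC-4180, header row) or JSON records.

    ``records`` may be a DataFrame or a list of homogeneous dicts; floats are
    serialized with at least 10 significant digits.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if df.empty:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.12g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=float)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")
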