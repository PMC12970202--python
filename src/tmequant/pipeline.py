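"""Reproducible pipeline orchestration: config, staging, and run reports.

A run reads (or simulates) fluorescence fields, segments cells and structure,
computes the spatial statistics, and optionally quantifies an angiography
volume and summarises a survival cohort.  Stage outputs carry anonymized
field identifiers; treatment-group labels are joined only in the final
report, emulating blinded image analysis.  The report is fully deterministic
given the config and seed (timestamps excluded by construction: none are
recorded).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .angiography import quantify_vessels
from .io import read_field, read_volume
from .segmentation import SegmentationParams, estimate_threshold, qc_flags, segment_area, segment_cells
from .spatial import cell_density, grid_occupancy, nearest_structure_distances, split_rich_poor
from .survival import SurvivalCohort, km_estimate, holm_adjust, logrank_test
from .synthetic import FieldSpec, generate_control_field, generate_field

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    cell_channel: str = "CD3"
    structure_channel: str = "aSMA"
    pixel_scale: float = 1.98
    field_paths: list[str] = field(default_factory=list)
    field_groups: list[str] = field(default_factory=list)
    channel_names: list[str] = field(default_factory=lambda: ["CD3", "aSMA"])
    simulate_fields: int = 0          # generate this many synthetic fields instead
    simulate_placements: list[str] = field(default_factory=list)
    control_path: str | None = None   # no-primary control TIFF for thresholds
    cell_threshold: float | None = None
    structure_threshold: float | None = None
    threshold_k: float = 3.0
    min_area_px: float = 5.0
    max_area_px: float = 5000.0
    min_solidity: float = 0.5
    max_eccentricity: float = 0.99
    grid_side_px: int = 100
    grid_mode: str = "centroid"
    bin_edges_um: list[float] = field(default_factory=lambda: [0.0, 20.0])
    volume_path: str | None = None
    voxel_size_um: float = 50.0
    angio_fraction: float = 0.5
    cohort_path: str | None = None
    survival_contrasts: list[list[str]] = field(default_factory=list)
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for p in [*self.field_paths, self.control_path, self.volume_path,
                  self.cohort_path]:
            if p is not None and not Path(p).exists():
                raise PipelineError("validate", f"input path does not exist: {p}")
        if not self.field_paths and not self.simulate_fields:
            if self.volume_path is None and self.cohort_path is None:
                raise PipelineError("validate", "config defines no inputs")
        if self.field_paths and self.field_groups and \
                len(self.field_groups) != len(self.field_paths):
            raise PipelineError("validate", "field_groups length mismatch")

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_fields(config: RunConfig):
    """Yield (field, group_label) pairs from paths or the simulator."""
    pairs = []
    if config.simulate_fields:
        placements = config.simulate_placements or ["uniform"]
        for i in range(config.simulate_fields):
            placement = placements[i % len(placements)]
            spec = FieldSpec(placement=placement, seed=config.seed + i,
                             pixel_scale=config.pixel_scale,
                             field_id=f"field_{i:03d}", group_label=placement)
            fld, _, _ = generate_field(spec)
            pairs.append((fld, placement))
    for i, path in enumerate(config.field_paths):
        group = config.field_groups[i] if config.field_groups else ""
        fld = read_field(path, config.channel_names,
                         pixel_scale=config.pixel_scale, group_label=group)
        pairs.append((fld, group))
    return pairs


def _thresholds(config: RunConfig):
    """Resolve cell/structure thresholds from config or a control image."""
    cell_thr, struct_thr = config.cell_threshold, config.structure_threshold
    if cell_thr is not None and struct_thr is not None:
        return cell_thr, struct_thr
    if config.control_path is not None:
        ctrl = read_field(config.control_path, config.channel_names,
                          pixel_scale=config.pixel_scale)
    elif config.simulate_fields:
        ctrl = generate_control_field(FieldSpec(seed=config.seed + 10_000,
                                                pixel_scale=config.pixel_scale))
    else:
        raise PipelineError("thresholds",
                            "no thresholds given and no control image available")
    if cell_thr is None:
        cell_thr = estimate_threshold(ctrl, config.cell_channel, k=config.threshold_k)
    if struct_thr is None:
        struct_thr = estimate_threshold(ctrl, config.structure_channel,
                                        k=config.threshold_k)
    return cell_thr, struct_thr


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and return the machine-readable report.

    Stages: segment -> spatial metrics -> (optional) angiography ->
    (optional) survival.  Any stage failure aborts with a stage-named error;
    outputs produced before the failure are retained in ``output_dir``.
    """
    config.validate()
    report: dict[str, Any] = {
        "tool": "tmequant",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    pairs = _load_fields(config)
    groups_by_id: dict[str, str] = {}

    if pairs:
        try:
            cell_thr, struct_thr = _thresholds(config)
            params = SegmentationParams(
                intensity_threshold=cell_thr,
                min_area_px=config.min_area_px, max_area_px=config.max_area_px,
                min_solidity=config.min_solidity,
                max_eccentricity=config.max_eccentricity)
            per_field = []
            masks = []
            for fld, group in pairs:
                groups_by_id[fld.field_id] = group
                cells = segment_cells(fld, config.cell_channel, params)
                mask = segment_area(fld, config.structure_channel, struct_thr)
                masks.append(mask)
                flags = qc_flags(fld)
                entry: dict[str, Any] = {
                    "field_id": fld.field_id,
                    "n_cells": len(cells),
                    "structure_area_fraction": mask.area_fraction,
                    "qc_flags": [f.flag for f in flags],
                    "density_cells_per_mm2": cell_density(
                        cells, fld.shape, config.pixel_scale),
                }
                if mask.mask.any() and len(cells):
                    dist = nearest_structure_distances(
                        cells, mask, config.pixel_scale,
                        bin_edges_um=config.bin_edges_um)
                    entry["mean_distance_um"] = dist.mean_um
                    entry["bin_fractions"] = [float(x) for x in dist.bin_fractions]
                else:
                    entry["mean_distance_um"] = None
                    entry["distance_flag"] = ("no_cells" if not len(cells)
                                              else "empty_structure_mask")
                occ = grid_occupancy(cells, mask, fld.shape,
                                     grid_side_px=config.grid_side_px,
                                     mode=config.grid_mode)
                entry["grid_occupancy"] = {
                    "n_grids": occ.n_grids, "n_positive": occ.n_positive,
                    "occupancy_fraction": occ.occupancy_fraction}
                per_field.append(entry)
            stage: dict[str, Any] = {
                "cell_threshold": float(cell_thr),
                "structure_threshold": float(struct_thr),
                "fields": per_field,
            }
            if len(masks) >= 2:
                part = split_rich_poor(masks)
                stage["rich_poor"] = {"rich": part.rich, "poor": part.poor,
                                      "cutoff": part.cutoff}
            report["stages"]["spatial"] = stage
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise PipelineError("spatial", str(exc)) from exc

    if config.volume_path is not None:
        try:
            vol = read_volume(config.volume_path, voxel_size_um=config.voxel_size_um)
            q = quantify_vessels(vol, fraction=config.angio_fraction)
            report["stages"]["angiography"] = {
                "volume_id": q.volume_id,
                "threshold_value": q.threshold_value,
                "positive_voxels": q.positive_voxels,
                "vessel_volume_mm3": q.vessel_volume_mm3,
            }
        except Exception as exc:
            raise PipelineError("angiography", str(exc)) from exc

    if config.cohort_path is not None:
        try:
            cohort = SurvivalCohort.from_csv(config.cohort_path)
            summaries = {}
            for grp in cohort.groups:
                s = km_estimate(cohort, grp)
                summaries[grp] = {
                    "n": s.n, "median_days": s.median_days,
                    "survivors_at_end": s.survivors_at_end,
                    "cure_rate_pct": s.cure_rate_pct,
                }
            contrasts = config.survival_contrasts or []
            raw_p = []
            tested = []
            for a, b in contrasts:
                res = logrank_test(cohort, a, b)
                tested.append({"groups": [a, b], "chi2": res.chi2,
                               "p": res.p, "defined": res.defined})
                if res.defined:
                    raw_p.append(res.p)
            if raw_p:
                adj = holm_adjust(raw_p, method="bonferroni")
                it = iter(adj)
                for t in tested:
                    if t["defined"]:
                        t["p_holm"] = float(next(it))
            report["stages"]["survival"] = {"groups": summaries,
                                            "logrank": tested}
        except Exception as exc:
            raise PipelineError("survival", str(exc)) from exc

    # group labels are joined only here, at reporting time
    if groups_by_id and "spatial" in report["stages"]:
        for entry in report["stages"]["spatial"]["fields"]:
            entry["group_label"] = groups_by_id.get(entry["field_id"], "")

    if out_dir:
        with open(out_dir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonify)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
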