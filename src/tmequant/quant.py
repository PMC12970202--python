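"""Closed-form quantification formulas: bead-corrected counts, per-gram
densities, and delta-delta-Ct relative expression.

Absolute cell counts from flow cytometry use counting beads spiked into the
sample: ``absolute = viable_cells * total_beads / counted_beads``.  Relative
qPCR expression uses the classical ddCt method with amplification efficiency
fixed at 2 (one doubling per cycle), normalized to a reference gene such as
beta-actin and expressed relative to a calibrator sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BeadCount",
    "DdctInput",
    "bead_corrected_count",
    "relative_expression",
    "per_gram_density",
]


@dataclass(frozen=True)
class BeadCount:
    viable_cells: float
    total_beads: float
    counted_beads: float

    @property
    def absolute_count(self) -> float:
        return bead_corrected_count(self.viable_cells, self.total_beads,
                                    self.counted_beads)


@dataclass(frozen=True)
class DdctInput:
    """Ct values for target and reference genes in sample and calibrator."""

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self):
        for name, ct in self.__dict__.items():
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError(f"{name} must be a finite positive cycle number")


def bead_corrected_count(viable: float, total_beads: float,
                         counted_beads: float) -> float:
    """Absolute cell count: ``viable * total_beads / counted_beads`` (unrounded)."""
    if counted_beads <= 0:
        raise ValueError("counted_beads must be positive")
    return viable * total_beads / counted_beads


def relative_expression(inp: DdctInput) -> float:
    """Fold change ``2^-ddCt`` with ``ddCt = dCt_sample - dCt_calibrator``."""
    dct_sample = inp.ct_target_sample - inp.ct_reference_sample
    dct_cal = inp.ct_target_calibrator - inp.ct_reference_calibrator
    return 2.0 ** (-(dct_sample - dct_cal))


def per_gram_density(absolute_count: float, tissue_mass_g: float) -> float:
    """Cells per gram of tissue."""
    if tissue_mass_g <= 0:
        raise ValueError("tissue mass must be positive")
    return absolute_count / tissue_mass_g
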