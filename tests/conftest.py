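import numpy as np
import pytest

from tmequant import FluorescenceField
from tmequant.segmentation import Cell, CellSet, RegionMask


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_field(channels, pixel_scale=1.0, field_id="f0"):
    return FluorescenceField(channels=channels, pixel_scale=pixel_scale,
                             field_id=field_id)


def make_cells(centroids, channel="CD3", field_id="f0"):
    cells = [Cell(label_id=i + 1, centroid_rc=(float(r), float(c)), area_px=10.0)
             for i, (r, c) in enumerate(centroids)]
    return CellSet(channel=channel, cells=cells, source_field_id=field_id)


def make_mask(mask, channel="aSMA", field_id="f0"):
    return RegionMask(channel=channel, mask=np.asarray(mask, dtype=bool),
                      source_field_id=field_id)
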