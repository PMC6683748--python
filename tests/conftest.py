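import numpy as np
import pytest

from clemux.segmentation import SegmentationParams, detect_cells, holes_mask
from clemux.synthetic import ChannelPanel, enumerate_patterns, render_sample


@pytest.fixture(scope="session")
def panel3():
    return ChannelPanel(("blue", "green", "red"))


@pytest.fixture(scope="session")
def patterns3(panel3):
    return enumerate_patterns(panel3)


@pytest.fixture(scope="session")
def em_sample(panel3, patterns3):
    """Small fully rendered sample (LM + EM + class map), 7 patterns x 4 cells."""
    return render_sample(panel3, patterns3, n_cells_per_pattern=4, seed=11)


@pytest.fixture(scope="session")
def em_params(em_sample):
    cfg_scale = 8.0  # matches RenderConfig default
    return SegmentationParams(pixel_size_nm=100.0 / cfg_scale)


@pytest.fixture(scope="session")
def detected(em_sample, em_params):
    """Detection output on the session sample (cells + holes raster)."""
    cells = detect_cells(em_sample.class_map, em_params)
    holes = holes_mask(em_sample.class_map, em_params)
    return cells, holes
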