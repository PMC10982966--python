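import numpy as np
import pytest
from hypothesis import settings

from gliotile.scheme import DEFAULT_SCHEME
from gliotile.synthetic import ROIAnnotation, SlideRecord, SyntheticConfig, generate_cohort
from gliotile.tiling import Tile

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def small_cohort():
    """8 synthetic slides at the test scale (64-px tiles), fully annotated."""
    cfg = SyntheticConfig(
        n_slides=8, tile_size=64, block_grid=(8, 6), difficulty=0.0, seed=42
    )
    return generate_cohort(cfg)


def make_slide(width=256, height=256, diagnosis="gbm", rois=(), image=None, slide_id="s0"):
    if image is None:
        image = np.zeros((height, width, 3), dtype=np.uint8)
    return SlideRecord(
        slide_id=slide_id,
        width=width,
        height=height,
        diagnosis=diagnosis,
        rois=list(rois),
        image=image,
    )


def make_tile(slide_id="s0", x=0, y=0, size=16, value=128, label=None, split="none"):
    pixels = np.full((size, size, 3), value, dtype=np.uint8)
    return Tile(slide_id=slide_id, x=x, y=y, size=size, pixels=pixels, label=label, split=split)


@pytest.fixture
def roi():
    return ROIAnnotation
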