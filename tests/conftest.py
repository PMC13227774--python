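import numpy as np
import pytest
from skimage import draw

from potpheno import synthetic
from potpheno.imaging import SegmentationConfig, extract_roi, segment_plant
from potpheno.morphometrics import ScaleCalibration


@pytest.fixture(scope="session")
def fan_render():
    """Default synthetic fan plant, its ground truth, and its spec."""
    spec = synthetic.PlantRenderSpec(seed=3)
    img, gt = synthetic.render_plant_image(spec)
    return img, gt, spec


@pytest.fixture(scope="session")
def fan_roi(fan_render):
    img, gt, spec = fan_render
    mask = segment_plant(
        img, SegmentationConfig(exclude_margin_px=synthetic.RULER_MARGIN_PX)
    )
    return extract_roi(img, mask), ScaleCalibration(spec.cm_per_pixel)


@pytest.fixture(scope="session")
def disc_mask():
    """Digitized disc of radius 100 px."""
    m = np.zeros((250, 250), bool)
    rr, cc = draw.disk((125, 125), 100)
    m[rr, cc] = True
    return m


@pytest.fixture(scope="session")
def rect_mask():
    """Filled axis-aligned 100 x 50 px rectangle."""
    m = np.zeros((80, 130), bool)
    m[10:60, 15:115] = True  # 50 rows x 100 cols
    return m


@pytest.fixture(scope="session")
def trial_table():
    return synthetic.simulate_trial(synthetic.TrialSimSpec(seed=1))


def random_blob_mask(rng: np.random.Generator, size: int = 40) -> np.ndarray:
    """Small random blob: union of a few random discs (always non-empty)."""
    m = np.zeros((size, size), bool)
    for _ in range(rng.integers(1, 4)):
        r = int(rng.integers(3, size // 4))
        cy, cx = rng.integers(r, size - r, 2)
        rr, cc = draw.disk((cy, cx), r)
        m[rr, cc] = True
    return m
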