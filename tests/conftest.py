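import numpy as np
import pytest

from weedmap import synthetic_field as sf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene():
    """A 64x64 labeled scene with all three classes present."""
    cfg = sf.SceneConfig(
        height=64, width=64, row_period=24, row_width=10,
        weed_patch_count_range=(2, 4), weed_patch_radius_range=(3, 8), seed=5,
    )
    return sf.generate_scene(cfg)


def boundary_noised_probabilities(gt: np.ndarray, rng: np.random.Generator,
                                  flip: float = 0.08, confidence: float = 0.85) -> np.ndarray:
    """Probability map that is right almost everywhere but noisy: a fraction
    of pixels gets a random (often wrong) winning class at the same confidence,
    mimicking boundary blur and salt noise in upsampled network outputs."""
    h, w = gt.shape
    p = np.full((h, w, 3), (1.0 - confidence) / 2)
    lab = gt.astype(np.int64).copy()
    m = rng.random((h, w)) < flip
    lab[m] = rng.integers(0, 3, int(m.sum()))
    p[np.arange(h)[:, None], np.arange(w)[None, :], lab] = confidence
    return p
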