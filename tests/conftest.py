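import numpy as np
import pytest

from hemibin import GrayHistogram, GrayImage, SceneParams, generate_scene


@pytest.fixture
def two_spike_hist() -> GrayHistogram:
    """Equal spikes at gray values 50 and 200."""
    counts = np.zeros(256, dtype=np.int64)
    counts[50] = 1000
    counts[200] = 1000
    return GrayHistogram.from_counts(counts)


@pytest.fixture
def two_triangle_hist() -> GrayHistogram:
    """Two triangular modes peaking at 90 and 170 with a single zero at 130."""
    counts = np.array(
        [max(0, 40 - abs(g - 90)) + max(0, 40 - abs(g - 170)) for g in range(256)],
        dtype=np.int64,
    )
    return GrayHistogram.from_counts(counts)


def mixture_histogram(rng: np.random.Generator, n: int = 20_000) -> np.ndarray:
    """A random two-normal mixture rounded onto [0, 255] (both modes occupied)."""
    w = rng.uniform(0.2, 0.8)
    n0 = int(n * w)
    lo = rng.normal(rng.uniform(30, 110), rng.uniform(5, 30), n0)
    hi = rng.normal(rng.uniform(140, 230), rng.uniform(5, 30), n - n0)
    vals = np.clip(np.rint(np.concatenate([lo, hi])), 0, 255).astype(np.int64)
    return np.bincount(vals, minlength=256)


@pytest.fixture
def default_scene():
    """A mid-sized scene with the default (histogram-exposed) parameters."""
    return generate_scene(SceneParams(width=256, height=256, seed=7))


@pytest.fixture
def auto_scene():
    """Same geometry, auto-exposed: saturated sky plus blooming."""
    return generate_scene(
        SceneParams(width=256, height=256, exposure="auto", seed=7)
    )


@pytest.fixture
def ramp_image() -> GrayImage:
    """Image containing every gray value many times (all strata populated)."""
    values = np.tile(np.arange(256, dtype=np.uint8), (128, 1))
    return GrayImage(values=values)
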