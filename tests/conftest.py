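import numpy as np
import pytest

from kymoclock import AxisSpec, IntensityMatrix, RoiMask, WaveModel, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_region_image():
    """100x40 image: value 10 for x < 50, 20 for x >= 50 (pixel centers)."""
    return np.where(np.arange(100)[None, :] + 0.5 < 50, 10.0, 20.0) * np.ones((40, 1))


@pytest.fixture
def straight_axis():
    """Horizontal axis along y=20, unit length 100 px: coordinate = x/100."""
    return AxisSpec(origin=[0.0, 20.0], polyline=[[0.0, 20.0], [100.0, 20.0]], unit_length=100.0)


@pytest.fixture
def box_roi():
    return RoiMask(polygon=[[5, 5], [95, 5], [95, 35], [5, 35]], sample_id="s1")


@pytest.fixture
def cosine_matrix():
    """12 samples, 20 rows r_i(j) = a_i + b_i cos(2 pi j / M): g = 0 closed form."""
    m, n = 12, 20
    rng = np.random.default_rng(7)
    j = np.arange(m)
    a = rng.uniform(2, 5, n)
    b = rng.uniform(0.5, 1.5, n)
    values = a[:, None] + b[:, None] * np.cos(2 * np.pi * j / m)
    return IntensityMatrix(
        values=values,
        bin_centers=(np.arange(n) + 0.5) / n,
        sample_ids=[f"s{k}" for k in range(m)],
        channel="Lfng_i",
    )


@pytest.fixture
def small_band_cohort():
    return simulate_cohort(
        WaveModel(mode="band", noise_fraction=0.05, n_bins=50), 8, seed=21, shuffle=True
    )
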