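import numpy as np
import pytest

from bloomatlas.synthetic import BloomTruth, generate_daily_field


@pytest.fixture
def clean_truth():
    """Noise-free, gap-free unimodal bloom: ground truth is exact."""
    return BloomTruth(baseline_chl=0.05, bloom_amplitude=0.5,
                      bloom_center_bin=30, bloom_width_bins=4,
                      noise_cv=0.0, gap_fraction=0.0, n_years=3, seed=7)


@pytest.fixture
def clean_field(clean_truth):
    field, _ = generate_daily_field(clean_truth, grid_shape=(4, 5))
    return field


@pytest.fixture
def rng():
    return np.random.default_rng(20240801)
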