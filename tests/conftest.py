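import numpy as np
import pytest

from mutscape.synthetic_data import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small complete synthetic study shared across tests (read-only)."""
    return generate_study(SyntheticConfig(
        n_chroms=2, chrom_length=1_000_000, window_width=50_000, seed=100))


@pytest.fixture(scope="session")
def bgc_study():
    """A synthetic study with a strong recombination-dependent fixation bias."""
    return generate_study(SyntheticConfig(
        n_chroms=2, chrom_length=2_500_000, window_width=20_000,
        bgc_strength=0.5, seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
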