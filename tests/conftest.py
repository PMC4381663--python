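import numpy as np
import pytest

from symratio.synthetic import SyntheticColonyConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_config():
    """One-colony study with zero Ct noise: quantification must be exact."""
    return SyntheticColonyConfig(
        n_colonies=1,
        population_mix=((0.1, 0.1, 0.8),),
        ct_noise_sd=0.0,
        tm_noise_sd=0.0,
        seed=42,
    )


@pytest.fixture
def study_config():
    """Full-size default study (6 colonies x 3 branches x 10 cells)."""
    return SyntheticColonyConfig(seed=7)
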