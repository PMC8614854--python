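import numpy as np
import pytest

from growthpf import GrowthParams, SyntheticSpec, generate


@pytest.fixture(scope="session")
def default_series():
    """Noisy single-regime Gompertz culture at the default study condition."""
    series, truth = generate(SyntheticSpec(seed=42))
    return series, truth[0]


@pytest.fixture(scope="session")
def noiseless_series():
    """Noise-free Gompertz culture with harvest well inside the run."""
    p = GrowthParams(2.0, 4.5, 0.9)
    series, _ = generate(SyntheticSpec(regimes=[(0.0, p)], noise_sd=0.0, seed=0))
    return series, p


@pytest.fixture
def rng():
    return np.random.default_rng(0)
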