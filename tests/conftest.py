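import numpy as np
import pytest

from barnflux.synthetic import GeneratorConfig, gen_study


@pytest.fixture(scope="session")
def tiny_study():
    """Two noisy days, small enough for fast unit tests."""
    return gen_study(GeneratorConfig(n_records=48, seed=7))


@pytest.fixture(scope="session")
def noiseless_study():
    """Noise-free campaign: the mass balance must invert it exactly."""
    return gen_study(
        GeneratorConfig(n_records=48, seed=7, snr=float("inf"), climate_noise=0.0)
    )


@pytest.fixture(scope="session")
def default_study():
    """The full default campaign: 718 hourly records, seed 42."""
    return gen_study(GeneratorConfig())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
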