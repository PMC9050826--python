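import numpy as np
import pytest

import branchwave as bw


@pytest.fixture(scope="session")
def params_c2() -> bw.ModelParams:
    return bw.ModelParams(c=2.0, r=0.0)


@pytest.fixture(scope="session")
def wave_18(params_c2) -> bw.WaveOrbit:
    """The noncritical reference wave: c=2, r=0, limits 1.8 / 0.2."""
    orbit = bw.shoot_wave(params_c2, 1.8)
    assert orbit.converged
    return orbit


@pytest.fixture(scope="session")
def wave_critical(params_c2) -> bw.WaveOrbit:
    """The critical invasion wave: c=2, r=0, limits 2 / 0, sub-exponential tail."""
    orbit = bw.shoot_wave(params_c2, 2.0)
    assert orbit.converged
    return orbit


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
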