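import numpy as np
import pytest

from duplextherm import ThermoParams
from duplextherm.simulate import SimulationConfig, generate_melting_curve


@pytest.fixture
def truth() -> ThermoParams:
    """A realistic 13-mer duplex: ΔH° = −92 kcal/mol, ΔS° = −258 cal/mol/K."""
    return ThermoParams(dH=-92.0, dS=-258.0)


@pytest.fixture
def noiseless_config(truth) -> SimulationConfig:
    return SimulationConfig(truth=truth, noise_sd=0.0, seed=0)


@pytest.fixture
def noiseless_curve(noiseless_config):
    return generate_melting_curve(noiseless_config, Ct=1e-5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140805)
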