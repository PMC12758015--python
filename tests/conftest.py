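import numpy as np
import pytest

from qusmigrate import rf_sim as rs


@pytest.fixture(scope="session")
def victim():
    return rs.victim_machine()


@pytest.fixture(scope="session")
def perp():
    return rs.perpetrator_machine()


@pytest.fixture(scope="session")
def phantoms():
    return [rs.phantom_liver_like(), rs.phantom_low_attenuation()]


@pytest.fixture(scope="session")
def cal_phantom():
    return rs.phantom_calibration()


@pytest.fixture(scope="session")
def victim_frame(victim):
    """One default-geometry victim frame, reused read-only across tests."""
    return rs.simulate_frame(victim, rs.phantom_liver_like(), seed=42)


@pytest.fixture(scope="session")
def noiseless_pair():
    """Noiseless stable calibration views of both machines sharing one
    phantom realization, perpetrator views already rate-matched."""
    from qusmigrate.preprocess import resample_rate

    v = rs.victim_machine(noise_floor=float("-inf"))
    p = rs.perpetrator_machine(noise_floor=float("-inf"))
    cv, cp = rs.simulate_calibration_views(v, p, rs.phantom_calibration(), 1, "stable", seed=11)
    return v, p, cv, [resample_rate(f, 4, 5) for f in cp]


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic two-machine study (simulated data, trained
    victim, fitted transfer function). Built once per session."""
    from qusmigrate.experiments import make_benchmark

    return make_benchmark(seed=1)
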