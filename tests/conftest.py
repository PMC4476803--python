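import numpy as np
import pytest

import sprbayes as sb


@pytest.fixture(scope="session")
def case_iv_scenario():
    """Standard scenario iv (MTLC = 3) on the default grid."""
    return sb.table1_scenarios(seed=0)[3]


@pytest.fixture(scope="session")
def case_iv_sensorgram(case_iv_scenario):
    return sb.simulate_sensorgram(case_iv_scenario)


@pytest.fixture(scope="session")
def toy_sensorgram():
    """Tiny two-phase sensorgram (cheap likelihood) for inference unit tests."""
    grid = sb.default_grid(assoc_duration=10.0, diss_duration=10.0, rate_hz=1.0)
    theta = sb.KineticState(ka=3e6, kd=3e-3, A0=30e-9, Rmax=31.5, sigma2=2.25)
    scn = sb.SimulationScenario(theta_true=theta, kM=3.15e7, noise_sd=1.5,
                                grid=grid, seed=11)
    return sb.simulate_sensorgram(scn)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
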