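import numpy as np
import pytest

import fueldry as fd
from fueldry.synthetic import noiseless


@pytest.fixture(scope="session")
def default_design() -> fd.ExperimentDesign:
    return fd.ExperimentDesign(seed=20260921)


@pytest.fixture(scope="session")
def noiseless_beds(default_design):
    """All five study beds simulated without measurement noise."""
    return fd.simulate_experiment(noiseless(default_design))


@pytest.fixture(scope="session")
def noisy_beds(default_design):
    """All five study beds at the default noise level (0.005 g/g)."""
    return fd.simulate_experiment(default_design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def exact_one_phase_curve(emc=0.162, amplitude=0.76, time_lag=12.5, step=1 / 6, duration=100.0):
    """A noise-free single-exponential curve on the 10-minute grid."""
    times = np.arange(0.0, duration + step / 2, step)
    params = fd.PhaseParams(emc=emc, amplitude=amplitude, time_lag=time_lag)
    return fd.DryingCurve(times=times, moisture=np.asarray(fd.eval_one_phase(params, times))), params
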