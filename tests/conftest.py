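import numpy as np
import pytest

from cgrcusum import (
    AggregateProcess,
    ExponentialBaseline,
    HospitalData,
    RiskModel,
    SubjectRecord,
    aggregate_processes,
)


@pytest.fixture
def exp_model():
    """Exponential baseline, rate 0.01/day, no risk adjustment."""
    return RiskModel(ExponentialBaseline(rate=0.01))


@pytest.fixture
def table1_model():
    """The null model of the run-length study: exponential rate 0.002/day."""
    return RiskModel(ExponentialBaseline(rate=0.002))


@pytest.fixture
def single_failure(exp_model):
    """One subject entering at 0, failing at day 10: N(10)=1, Lambda(10)=0.1."""
    hosp = HospitalData("single", [SubjectRecord("s1", 0.0, 10.0, True)], horizon=10.0)
    return aggregate_processes(hosp, exp_model)


def random_aggregate(rng, model, n_max=8, horizon=120.0):
    """Small random stream of subjects for brute-force comparisons."""
    n = int(rng.integers(1, n_max + 1))
    entry = np.sort(rng.uniform(0, horizon / 2, n))
    dur = rng.uniform(0.5, horizon, n)
    event = rng.random(n) < 0.6
    return AggregateProcess(entry, dur, event, np.ones(n), model)
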