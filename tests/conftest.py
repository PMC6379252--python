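import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gradedif import (
    SimulationSpec,
    fit_grm,
    load_bdi2_bank,
    simulate_responses,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STUDY_SEED = 42


@pytest.fixture(scope="session")
def bank():
    return load_bdi2_bank()


@pytest.fixture(scope="session")
def study_sim(bank):
    """N=12,677 responses drawn from the packaged bank, theta ~ N(0,1)."""
    return simulate_responses(
        SimulationSpec(n_persons=12_677, item_bank=bank, seed=STUDY_SEED)
    )


@pytest.fixture(scope="session")
def study_fit(study_sim):
    """MML-EM recalibration of the simulated study-sized dataset."""
    return fit_grm(study_sim)


@pytest.fixture(scope="session")
def toy_bank():
    """Small 5-item bank for fast recovery and scoring tests."""
    from gradedif import GRMItem, ItemBank

    return ItemBank(
        items=[
            GRMItem(a=1.8, b=(-1.0, 0.0, 1.2), label="t1"),
            GRMItem(a=1.2, b=(-0.5, 0.8, 2.0), label="t2"),
            GRMItem(a=2.5, b=(0.2, 1.0, 1.8), label="t3"),
            GRMItem(a=0.9, b=(-1.5, -0.2, 0.9), label="t4"),
            GRMItem(a=1.5, b=(0.0, 1.5, 2.5), label="t5"),
        ]
    )
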