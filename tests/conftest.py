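import numpy as np
import pytest

from igtrl.cohort import StudyDesign, generate_cohort
from igtrl.models import PVLParams, simulate_agent
from igtrl.task import build_payoff_schedule


@pytest.fixture(scope="session")
def schedule():
    return build_payoff_schedule()


@pytest.fixture(scope="session")
def example_session(schedule):
    params = PVLParams(alpha=0.4, lam=1.2, A=0.6, c=1.0)
    return simulate_agent(params, schedule, "pvl_decay", n_trials=100, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Four tiny groups, short sessions — for structural/IO tests."""
    design = StudyDesign.default(seed=7, n_trials=40, group_sizes=(3, 3, 3, 3))
    return generate_cohort(design)


def random_pvl_params(rng: np.random.Generator) -> PVLParams:
    return PVLParams(
        alpha=float(rng.uniform(0.05, 0.95)),
        lam=float(rng.uniform(0.05, 4.5)),
        A=float(rng.uniform(0.05, 0.95)),
        c=float(rng.uniform(0.05, 3.0)),
    )
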