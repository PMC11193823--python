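import numpy as np
import pandas as pd
import pytest

from rlexpect.task import default_design


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def trials_frame(rows, subject_id=1, group=0):
    """Build a minimal trial table from (pair, choice, reward) tuples."""
    design_ = default_design()
    records = []
    for t, (pair, choice, reward) in enumerate(rows, start=1):
        p = design_.pair(pair)
        records.append(
            {
                "subject_id": subject_id,
                "group": group,
                "trial": t,
                "pair": pair,
                "choice": choice,
                "optimal": int(choice == p.stim_better),
                "reward": reward,
            }
        )
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def small_cohort_table():
    """A 12-subject simulated SWo cohort reused by slower integration tests."""
    from rlexpect.cohort import draw_cohort, make_scenario, simulate_cohort

    scenario = make_scenario("inverted_u", "SWo", 12)
    cohort = draw_cohort(scenario, 202)
    table = simulate_cohort(cohort, seed=203)
    return cohort, table
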