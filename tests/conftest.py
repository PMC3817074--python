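import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import stuntquant as sq

RECOVERY_ROLES = {
    "child_age": {"kind": "continuous"},
    "sex": {"kind": "categorical", "reference": "male",
            "levels": ["male", "female"]},
    "wealth": {"kind": "categorical", "reference": "poorest",
               "levels": ["poorest", "poorer", "middle", "richer", "richest"]},
    "twin": {"kind": "categorical", "reference": "no", "levels": ["no", "yes"]},
    "null_cat": {"kind": "categorical", "reference": "a", "levels": ["a", "b"]},
    "region": {"kind": "spatial"},
}


@pytest.fixture(scope="session")
def recovery_cohort():
    """One parameter-recovery cohort (n=2000) plus its graph and learners."""
    spec, graph = sq.recovery_scenario(n=2000, seed=0)
    table = sq.simulate_cohort(spec, graph)
    config = sq.ModelConfig(covariates=RECOVERY_ROLES, seed=0)
    learners = sq.build_learners(config, table, graph)
    return spec, graph, table, config, learners


@pytest.fixture(scope="session")
def fitted_q35(recovery_cohort):
    """A tau=0.35 model fitted to the recovery cohort at a CV-chosen mstop."""
    spec, graph, table, config, learners = recovery_cohort
    loss = sq.LossSpec("quantile", 0.35)
    y = table["haz"].to_numpy()
    cv = sq.cross_validate_mstop(table, y, learners, loss, folds=5,
                                 grid=tuple(range(0, 1501, 50)), seed=1)
    model = sq.boost(table, y, learners, loss, mstop=cv.mstop, nu=0.2)
    return model, cv


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
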