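import numpy as np
import pytest

from qvcv import (
    cohort_feature_matrix,
    fit_pta_model,
    packaged_default_panel,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return packaged_default_panel()


@pytest.fixture(scope="session")
def excess_cohort(panel):
    """A 60-listener cohort with a 7-listener excess-loss subgroup."""
    trials, metas, profiles = simulate_cohort(
        15,
        panel=panel,
        trials_per_token=5,
        n_sessions=2,
        excess_fraction=7 / 60,
        excess_delta_db=10.0,
        seed=11,
    )
    ids, X = cohort_feature_matrix(trials, panel)
    prof = {p.listener_id: p for p in profiles}
    return {
        "trials": trials,
        "metas": {m.listener_id: m for m in metas},
        "profiles": prof,
        "ids": ids,
        "X": X,
        "true_pta": np.array([prof[i].true_pta_db_hl for i in ids]),
        "excess": np.array([prof[i].excess_offset_db for i in ids]),
    }


@pytest.fixture(scope="session")
def fitted_model(excess_cohort):
    """PTA model fitted on the shared cohort, with CV predictions."""
    model, ppta_cv = fit_pta_model(
        excess_cohort["X"],
        excess_cohort["true_pta"],
        hl_labels=(excess_cohort["true_pta"] > 15).astype(int),
        lam=3.0,
        n_repeats=100,
        seed=12,
    )
    return model, ppta_cv
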