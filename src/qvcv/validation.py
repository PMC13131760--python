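"""Reference validation studies on calibrated synthetic cohorts.

Each study simulates a cohort under the standard conditions (Table-1-style
composition: 15 listeners per hearing category, 100-trial sessions twice,
packaged panel at calibrated SNRs), runs the corresponding analysis, and
returns the headline metric: cross-validated PPTA error, residual-loss
recovery, excess-loss detectability, and normal-hearing score
normalization.  These are the quantities the package's accuracy claims rest
on; ``scripts/acceptance.py`` and the acceptance tests both run them.
"""

from __future__ import annotations

import numpy as np

from .core import build_confusion_matrix, score_percent_correct
from .listener_sim import simulate_cohort
from .pta_model import (
    cohort_feature_matrix,
    excess_loss_auc,
    fit_audibility,
    fit_pta_model,
)
from .token_selection import packaged_default_panel

N_PER_CATEGORY = 15
TRIALS_PER_TOKEN = 5   # x 2 recordings x 2 sessions = 200 trials/listener
N_SESSIONS = 2
N_EXCESS = 7
EXCESS_DELTA_DB = 10.0
LAMBDA = 3.0
N_CV_REPEATS = 100


def _cohort(seed: int, excess: bool):
    panel = packaged_default_panel()
    trials, metas, profiles = simulate_cohort(
        N_PER_CATEGORY,
        panel=panel,
        trials_per_token=TRIALS_PER_TOKEN,
        n_sessions=N_SESSIONS,
        excess_fraction=(N_EXCESS / (4 * N_PER_CATEGORY)) if excess else 0.0,
        excess_delta_db=EXCESS_DELTA_DB,
        seed=seed,
    )
    ids, X = cohort_feature_matrix(trials, panel)
    prof = {p.listener_id: p for p in profiles}
    y = np.array([prof[i].true_pta_db_hl for i in ids])
    offsets = np.array([prof[i].excess_offset_db for i in ids])
    return panel, trials, X, y, offsets


def cv_ppta_mae_study(seed: int) -> float:
    """Cross-validated mean absolute PPTA error (dB) on a clean cohort."""
    _, _, X, y, _ = _cohort(seed, excess=False)
    _, ppta = fit_pta_model(
        X, y, lam=LAMBDA, n_repeats=N_CV_REPEATS, seed=2**16 + seed
    )
    return float(np.abs(ppta - y).mean())


def residual_loss_study(seed: int) -> dict[str, float]:
    """Residual-loss recovery and excess detectability on an excess cohort.

    Returns the mean |estimated RHL - injected offset| in dB and the
    cross-validated AUC for predicting excess status from confusion
    features alone.
    """
    _, _, X, y, offsets = _cohort(seed, excess=True)
    _, ppta = fit_pta_model(
        X, y, lam=LAMBDA, n_repeats=N_CV_REPEATS, seed=2**17 + seed
    )
    audibility = fit_audibility(y, ppta)
    rhl = ppta - audibility(y)
    auc = excess_loss_auc(
        X, (offsets > 0).astype(int), lam=LAMBDA, seed=2**18 + seed
    )
    return {
        "rhl_mae_db": float(np.abs(rhl - offsets).mean()),
        "excess_auc": float(auc),
        "audibility_floor_db_hl": audibility.floor_db_hl,
    }


def nh_normalization_study(seed: int, n_listeners: int = 20) -> float:
    """Mean percent correct of a normal-hearing cohort at panel SNRs."""
    panel = packaged_default_panel()
    trials, _, _ = simulate_cohort(
        {"NH": n_listeners},
        panel=panel,
        trials_per_token=TRIALS_PER_TOKEN,
        n_sessions=N_SESSIONS,
        seed=seed,
    )
    by_listener: dict[str, list] = {}
    for t in trials:
        by_listener.setdefault(t.listener_id, []).append(t)
    scores = [
        score_percent_correct(
            build_confusion_matrix(ts, presented_labels=panel.consonants)
        )
        for ts in by_listener.values()
    ]
    return float(np.mean(scores))
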