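"""Test-retest repeatability and test-time efficiency.

Repeatability of the test is summarized by the Pearson correlation and the
mean absolute difference (MAD) between paired sessions, and by how the MAD
shrinks as more trials are scored.  The trial-count curve is estimated by
token-balanced random subsampling of each session (so a t-trial subtest is
still a balanced mini-panel), with percentile confidence intervals over
resamples.  Published reference constants for the comparison sentence test
are packaged for plotting against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr

from .core import TrialRecord, build_confusion_matrix, score_percent_correct
from .token_selection import TokenPanel


def quicksin_reference() -> dict[str, float]:
    """Published reference constants for repeatability comparisons."""
    return {
        "quicksin_repeatability_db": 2.5,
        "qvcv_repeatability_db": 5.0,
        "trials_per_minute": 25,
        "quicksin_list_minutes": 1,
    }


@dataclass(frozen=True)
class PairStats:
    pearson_r: float
    mad: float
    flagged: bool = False  # correlation undefined (zero variance)


def session_pair_stats(
    scores1: Sequence[float], scores2: Sequence[float]
) -> PairStats:
    """Pearson r and mean |difference| between paired session scores."""
    a = np.asarray(scores1, dtype=float)
    b = np.asarray(scores2, dtype=float)
    if a.size != b.size:
        raise ValueError("paired score lists must have equal length")
    if a.size < 3:
        raise ValueError("need >= 3 paired listeners")
    mad = float(np.abs(a - b).mean())
    if a.std() == 0 or b.std() == 0:
        return PairStats(pearson_r=float("nan"), mad=mad, flagged=True)
    r = float(pearsonr(a, b).statistic)
    return PairStats(pearson_r=r, mad=mad)


def stratified_subsample(
    trials: Sequence[TrialRecord],
    t: int,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Subsample t trials without replacement, balanced over tokens.

    Tokens are (consonant, recording) pairs; per-token counts of the
    subsample differ by at most one for any t.
    """
    by_token: dict[tuple, list[int]] = {}
    for i, tr in enumerate(trials):
        by_token.setdefault((tr.consonant, tr.vowel, tr.recording), []).append(i)
    if t > len(trials):
        raise ValueError(f"t={t} exceeds session length {len(trials)}")
    tokens = sorted(by_token)
    base, extra = divmod(t, len(tokens))
    quota = {k: base for k in tokens}
    if extra:
        for k in rng.permutation(len(tokens))[:extra]:
            quota[tokens[k]] += 1
    picked: list[int] = []
    for k in tokens:
        idx = by_token[k]
        if quota[k] > len(idx):
            raise ValueError(
                f"token {k} has only {len(idx)} trials, need {quota[k]}"
            )
        picked.extend(rng.choice(idx, size=quota[k], replace=False))
    return [trials[i] for i in sorted(picked)]


@dataclass
class RepeatabilityCurve:
    """MAD between sessions as a function of scored trial count."""

    trial_counts: list[int]
    mad_percent: list[tuple[float, float, float]]  # (mean, lo, hi)
    mad_ppta_db: list[tuple[float, float, float]] | None
    n_listeners: int
    n_resamples: int
    seed: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, t in enumerate(self.trial_counts):
            m, lo, hi = self.mad_percent[i]
            row = {
                "n_trials": t,
                "test_minutes": t / quicksin_reference()["trials_per_minute"],
                "mad_percent": m,
                "mad_percent_lo": lo,
                "mad_percent_hi": hi,
            }
            if self.mad_ppta_db is not None:
                md, lod, hid = self.mad_ppta_db[i]
                row.update(mad_ppta_db=md, mad_ppta_db_lo=lod, mad_ppta_db_hi=hid)
            rows.append(row)
        return pd.DataFrame(rows)


def mad_vs_trials(
    trials: Iterable[TrialRecord],
    trial_counts: Sequence[int],
    n_resamples: int = 200,
    seed: int = 0,
    model=None,
    panel: TokenPanel | None = None,
    session_ids: tuple[str, str] = ("s1", "s2"),
    method: str = "subsample",
    ci: tuple[float, float] = (2.5, 97.5),
) -> RepeatabilityCurve:
    """Repeatability (MAD across listeners) as a function of trial count.

    For each count t and each resample, a token-balanced subsample of t
    trials is drawn per session per listener and scored; with a fitted PTA
    model (and panel) the PPTA MAD is computed alongside the percent-correct
    MAD.  ``method='truncate'`` takes the first t trials instead of
    sampling.
    """
    from .pta_model import predict_ppta, vectorize_ccm

    by_listener: dict[str, dict[str, list[TrialRecord]]] = {}
    for tr in trials:
        by_listener.setdefault(tr.listener_id, {}).setdefault(tr.session_id, []).append(tr)
    listeners = sorted(by_listener)
    for lid in listeners:
        for sid in session_ids:
            if sid not in by_listener[lid]:
                raise ValueError(f"listener {lid} lacks session {sid}")
            if max(trial_counts) > len(by_listener[lid][sid]):
                raise ValueError(
                    f"t={max(trial_counts)} exceeds session length "
                    f"{len(by_listener[lid][sid])} for {lid}/{sid}"
                )
    rng = np.random.default_rng(seed)
    labels = panel.consonants if panel is not None else None

    def score_subset(subset: list[TrialRecord]):
        cm = build_confusion_matrix(subset, presented_labels=labels)
        pct = score_percent_correct(cm)
        if model is None:
            return pct, None
        return pct, predict_ppta(model, vectorize_ccm(cm))

    mad_pct_all = np.empty((len(trial_counts), n_resamples))
    mad_db_all = np.empty((len(trial_counts), n_resamples)) if model else None
    for ti, t in enumerate(trial_counts):
        for r in range(n_resamples):
            d_pct, d_db = [], []
            for lid in listeners:
                vals = []
                for sid in session_ids:
                    sess = by_listener[lid][sid]
                    if method == "truncate":
                        subset = sess[:t]
                    else:
                        subset = stratified_subsample(sess, t, rng)
                    vals.append(score_subset(subset))
                d_pct.append(abs(vals[0][0] - vals[1][0]))
                if model is not None:
                    d_db.append(abs(vals[0][1] - vals[1][1]))
            mad_pct_all[ti, r] = np.mean(d_pct)
            if model is not None:
                mad_db_all[ti, r] = np.mean(d_db)

    def summarize(arr):
        return [
            (
                float(arr[i].mean()),
                float(np.percentile(arr[i], ci[0])),
                float(np.percentile(arr[i], ci[1])),
            )
            for i in range(len(trial_counts))
        ]

    return RepeatabilityCurve(
        trial_counts=list(trial_counts),
        mad_percent=summarize(mad_pct_all),
        mad_ppta_db=summarize(mad_db_all) if model is not None else None,
        n_listeners=len(listeners),
        n_resamples=n_resamples,
        seed=seed,
    )
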