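"""Stimulus-panel optimization: AUC screening and token selection.

Discriminability of each token for hearing loss is quantified as the
Mann-Whitney AUC between per-listener proportion-correct scores of
normal-hearing (PTA <= 15 dB HL) and hearing-loss listeners.  Consonants
whose AUC falls below threshold are dropped, the vowel context with the
highest (least variable) AUC is kept, and each retained token is assigned
its most discriminative SNR.  The packaged default panel is the final
ten-consonant /ɑ/ set with its per-token SNRs and AUCs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core import CONSONANTS, OTHER, ListenerMeta, TrialRecord

#: Listeners with PTA above this are "hearing loss" for screening purposes.
NH_CUTOFF_DB_HL = 15.0

DEFAULT_AUC_THRESHOLD = 0.9

# The final optimized panel: consonant -> (SNR dB, AUC).  AUCs were reported
# as rounded percentages; stored here as fractions.
_DEFAULT_PANEL = {
    "b": (15, 0.96),
    "d": (4, 0.98),
    "g": (3, 0.94),
    "k": (0, 0.89),
    "n": (15, 1.00),
    "s": (0, 0.94),
    "ʃ": (0, 0.98),
    "t": (0, 0.99),
    "v": (15, 0.95),
    "z": (0, 0.98),
}
DEFAULT_PANEL_VOWEL = "ɑ"


@dataclass(frozen=True)
class PanelEntry:
    consonant: str
    vowel: str
    snr_db: int
    auc: float


@dataclass
class TokenPanel:
    """The selected consonant set with per-token SNR and AUC."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        keys = [(e.consonant, e.vowel) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (consonant, vowel) in panel")
        for e in self.entries:
            if not 0.0 <= e.auc <= 1.0:
                raise ValueError("AUC must be in [0, 1]")
            if e.snr_db != int(e.snr_db):
                raise ValueError("panel SNRs must be integer dB")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, consonant: str) -> PanelEntry:
        for e in self.entries:
            if e.consonant == consonant:
                return e
        raise KeyError(consonant)

    @property
    def consonants(self) -> tuple[str, ...]:
        """Distinct consonants in panel order (vowel contexts collapsed)."""
        seen = dict.fromkeys(e.consonant for e in self.entries)
        return tuple(seen)

    @property
    def response_set(self) -> tuple[str, ...]:
        """Response choices for modeling: panel consonants + OTHER."""
        return self.consonants + (OTHER,)

    def snr_for(self, consonant: str) -> int:
        return self[consonant].snr_db

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "qvcv-panel",
                "version": 1,
                "entries": [
                    {
                        "consonant": e.consonant,
                        "vowel": e.vowel,
                        "snr_db": e.snr_db,
                        "auc": e.auc,
                    }
                    for e in self.entries
                ],
            },
            ensure_ascii=False,
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TokenPanel":
        obj = json.loads(text)
        if obj.get("format") != "qvcv-panel":
            raise ValueError("not a panel file")
        return cls(
            entries=tuple(
                PanelEntry(d["consonant"], d["vowel"], int(d["snr_db"]), float(d["auc"]))
                for d in obj["entries"]
            )
        )


def packaged_default_panel() -> TokenPanel:
    """The packaged 10-consonant /ɑ/ panel with optimized SNRs and AUCs."""
    return TokenPanel(
        entries=tuple(
            PanelEntry(c, DEFAULT_PANEL_VOWEL, snr, auc)
            for c, (snr, auc) in _DEFAULT_PANEL.items()
        )
    )


def auc_mann_whitney(scores_nh: Sequence[float], scores_hl: Sequence[float]) -> float:
    """AUC = P(random HL score < random NH score), ties counted 1/2.

    Computed as the Mann-Whitney U statistic (NH over HL) divided by
    n_nh * n_hl, so that hearing-loss listeners scoring worse gives
    AUC > 0.5 and perfect separation gives 1.0.
    """
    nh = np.asarray(scores_nh, dtype=float)
    hl = np.asarray(scores_hl, dtype=float)
    if nh.size == 0 or hl.size == 0:
        raise ValueError("both groups must be non-empty")
    u = mannwhitneyu(nh, hl, alternative="two-sided", method="asymptotic").statistic
    return float(u) / (nh.size * hl.size)


def per_listener_token_scores(
    trials: Iterable[TrialRecord],
    meta: Mapping[str, ListenerMeta] | Iterable[ListenerMeta],
) -> pd.DataFrame:
    """Per-listener proportion correct for every (consonant, vowel, snr) token.

    Returns a tidy frame with columns listener_id, consonant, vowel, snr_db,
    n, k, score, group ('NH' if PTA <= 15 dB HL else 'HL').
    """
    if not isinstance(meta, Mapping):
        meta = {m.listener_id: m for m in meta}
    rows = {}
    for t in trials:
        key = (t.listener_id, t.consonant, t.vowel, t.snr_db)
        n, k = rows.get(key, (0, 0))
        rows[key] = (n + 1, k + int(t.correct))
    records = []
    for (lid, cons, vow, snr), (n, k) in sorted(rows.items()):
        m = meta[lid]
        records.append(
            {
                "listener_id": lid,
                "consonant": cons,
                "vowel": vow,
                "snr_db": snr,
                "n": n,
                "k": k,
                "score": k / n,
                "group": "NH" if m.measured_pta_db_hl <= NH_CUTOFF_DB_HL else "HL",
            }
        )
    return pd.DataFrame.from_records(records)


def _group_auc(frame: pd.DataFrame) -> float:
    nh = frame.loc[frame["group"] == "NH", "score"].to_numpy()
    hl = frame.loc[frame["group"] == "HL", "score"].to_numpy()
    return auc_mann_whitney(nh, hl)


def bootstrap_auc(
    scores_nh: Sequence[float],
    scores_hl: Sequence[float],
    n_resamples: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap (over listeners) distribution of the Mann-Whitney AUC."""
    rng = np.random.default_rng(rng)
    nh = np.asarray(scores_nh, dtype=float)
    hl = np.asarray(scores_hl, dtype=float)
    out = np.empty(n_resamples)
    for i in range(n_resamples):
        out[i] = auc_mann_whitney(
            rng.choice(nh, nh.size, replace=True),
            rng.choice(hl, hl.size, replace=True),
        )
    return out


def screen_consonants(
    per_token_scores: pd.DataFrame,
    threshold_auc: float = DEFAULT_AUC_THRESHOLD,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Drop consonants whose discriminability AUC falls below threshold.

    A consonant's AUC is the median over its (vowel, SNR) token AUCs; the
    report lists every token AUC so the per-consonant distributions remain
    inspectable.
    """
    present = set(per_token_scores["consonant"])
    missing = [c for c in CONSONANTS if c not in present]
    if missing:
        raise ValueError(f"scores missing for consonants: {missing}")
    rows = []
    for (cons, vow, snr), grp in per_token_scores.groupby(
        ["consonant", "vowel", "snr_db"], sort=True
    ):
        rows.append(
            {"consonant": cons, "vowel": vow, "snr_db": snr, "auc": _group_auc(grp)}
        )
    report = pd.DataFrame(rows)
    med = report.groupby("consonant")["auc"].median()
    report = report.merge(
        med.rename("consonant_auc"), left_on="consonant", right_index=True
    )
    retained = tuple(c for c in CONSONANTS if med[c] >= threshold_auc)
    return retained, report


def select_vowel(
    per_vowel_aucs: Mapping[str, Sequence[float]],
) -> tuple[str, pd.DataFrame]:
    """Pick the vowel context maximizing median AUC.

    Ties break toward the lower interquartile range (less variable), then
    alphabetically.
    """
    if not per_vowel_aucs:
        raise ValueError("no vowel AUC distributions supplied")
    rows = []
    for vowel, aucs in per_vowel_aucs.items():
        a = np.asarray(aucs, dtype=float)
        q1, q3 = np.percentile(a, [25, 75])
        rows.append(
            {"vowel": vowel, "median_auc": float(np.median(a)), "iqr": float(q3 - q1)}
        )
    report = pd.DataFrame(rows).sort_values("vowel").reset_index(drop=True)
    best = sorted(
        report.itertuples(), key=lambda r: (-r.median_auc, r.iqr, r.vowel)
    )[0]
    return best.vowel, report


def select_snr_per_token(
    candidate_aucs: Mapping[tuple[str, str], Sequence[tuple[float, float]]],
) -> dict[tuple[str, str], int]:
    """Pick the argmax-AUC SNR per token; ties break toward the lower SNR."""
    out = {}
    for token, cands in candidate_aucs.items():
        if not cands:
            raise ValueError(f"no candidate SNRs for token {token}")
        snr, _ = sorted(cands, key=lambda sa: (-sa[1], sa[0]))[0]
        out[token] = int(round(snr))
    return out


def build_panel(
    per_token_scores: pd.DataFrame,
    threshold_auc: float = DEFAULT_AUC_THRESHOLD,
    n_bootstrap: int = 1000,
    seed: int | None = 0,
) -> tuple[TokenPanel, dict]:
    """End-to-end selection: screen consonants, pick a vowel, pick SNRs.

    Per-vowel AUC distributions (for the vowel choice) are bootstrap
    resamples over listeners of the all-retained-consonant AUC within each
    vowel context.  Returns the panel plus a report dict of intermediates.
    """
    rng = np.random.default_rng(seed)
    retained, consonant_report = screen_consonants(per_token_scores, threshold_auc)
    kept = per_token_scores[per_token_scores["consonant"].isin(retained)]

    per_vowel = {}
    for vowel, grp in kept.groupby("vowel"):
        by_listener = grp.groupby(["listener_id", "group"], as_index=False)["score"].mean()
        nh = by_listener.loc[by_listener["group"] == "NH", "score"]
        hl = by_listener.loc[by_listener["group"] == "HL", "score"]
        per_vowel[vowel] = bootstrap_auc(nh, hl, n_bootstrap, rng)
    vowel, vowel_report = select_vowel(per_vowel)

    in_vowel = kept[kept["vowel"] == vowel]
    candidates: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for (cons, snr), grp in in_vowel.groupby(["consonant", "snr_db"]):
        candidates.setdefault((cons, vowel), []).append((snr, _group_auc(grp)))
    snr_choice = select_snr_per_token(candidates)

    entries = []
    for cons in retained:
        snr = snr_choice[(cons, vowel)]
        auc = max(a for s, a in candidates[(cons, vowel)] if int(round(s)) == snr)
        entries.append(PanelEntry(cons, vowel, snr, round(auc, 4)))
    panel = TokenPanel(entries=tuple(entries))
    report = {
        "retained_consonants": retained,
        "consonant_report": consonant_report,
        "vowel": vowel,
        "vowel_report": vowel_report,
        "snr_choice": snr_choice,
    }
    return panel, report
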