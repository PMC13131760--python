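"""Core data model for closed-set consonant-identification trials.

The test presents vowel-consonant-vowel (VCV) tokens in speech-shaped noise
and asks the listener to identify the consonant from a fixed set of buttons.
This module defines the trial record, the presented-by-response confusion
matrix with its percent-correct scoring view, listener metadata, and the
audiometric hearing-category bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

# The 13 candidate consonants of the closed set, canonical IPA order.
CONSONANTS: tuple[str, ...] = (
    "b", "d", "g", "p", "t", "k", "v", "z", "f", "s", "ʃ", "m", "n",
)
VOWELS: tuple[str, ...] = ("ɑ", "i", "u")

#: Explicit non-consonant response ("other" / "???" button); always incorrect.
OTHER = "OTHER"

# ASCII aliases used in session files; canonical IPA is used internally.
ASCII_TO_IPA = {"sh": "ʃ", "a": "ɑ", "other": OTHER, "???": OTHER}
IPA_TO_ASCII = {"ʃ": "sh", "ɑ": "a", OTHER: "other"}

#: Aided-condition labels.
AIDED_CONDITIONS = ("unaided", "lab_aid", "personal_aid")

#: Hearing-category bands in dB HL (inclusive), on the 3-frequency
#: (1, 2, 4 kHz) pure-tone average. PTA above 55 dB HL is an exclusion.
CATEGORY_BANDS: dict[str, tuple[int, int]] = {
    "NH": (-10, 15),
    "slight": (16, 25),
    "mild": (26, 40),
    "moderate": (41, 55),
}
CATEGORIES = tuple(CATEGORY_BANDS)

PTA_MIN, PTA_MAX = -10, 55


def canonical_label(label: str) -> str:
    """Map an ASCII alias ('sh', 'a', 'other', '???') to its canonical form."""
    return ASCII_TO_IPA.get(label, label)


def ascii_label(label: str) -> str:
    """Map a canonical label to its file-portable ASCII form."""
    return IPA_TO_ASCII.get(label, label)


@dataclass(frozen=True)
class TrialRecord:
    """One closed-set identification trial."""

    listener_id: str
    session_id: str
    block: int
    consonant: str
    vowel: str
    recording: int
    snr_db: float
    response: str
    aided: str = "unaided"

    def __post_init__(self) -> None:
        if self.consonant not in CONSONANTS:
            raise ValueError(f"unknown consonant {self.consonant!r}")
        if self.vowel not in VOWELS:
            raise ValueError(f"unknown vowel {self.vowel!r}")
        if self.response != OTHER and self.response not in CONSONANTS:
            raise ValueError(f"unknown response {self.response!r}")
        if self.recording not in (1, 2):
            raise ValueError("recording must be 1 or 2")
        if self.block < 1:
            raise ValueError("block must be >= 1")
        if not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.aided not in AIDED_CONDITIONS:
            raise ValueError(f"unknown aided condition {self.aided!r}")

    @property
    def correct(self) -> bool:
        """Correct iff the response matches the presented consonant.

        The OTHER button can never match, hence is always incorrect.
        """
        return self.response == self.consonant


@dataclass(frozen=True)
class ListenerMeta:
    """Audiometric metadata for one listener (better-ear test ear)."""

    listener_id: str
    measured_pta_db_hl: float
    category: str = ""
    test_ear: str = "right"

    def __post_init__(self) -> None:
        cat = assign_category(self.measured_pta_db_hl)
        if self.category == "":
            object.__setattr__(self, "category", cat)
        elif self.category != cat:
            raise ValueError(
                f"category {self.category!r} inconsistent with "
                f"PTA {self.measured_pta_db_hl} dB HL (expected {cat!r})"
            )


@dataclass
class ConfusionMatrix:
    """Presented-consonant x response-choice count matrix.

    ``counts[i, j]`` is the number of trials in which consonant
    ``presented_labels[i]`` was presented and ``response_labels[j]`` was
    chosen.  ``response_labels`` extends ``presented_labels`` with extra
    response choices (typically OTHER, which absorbs off-panel buttons).
    """

    presented_labels: tuple[str, ...]
    response_labels: tuple[str, ...]
    counts: np.ndarray
    listener_id: str = ""
    aided: str = "unaided"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.presented_labels), len(self.response_labels)):
            raise ValueError("counts shape does not match label lists")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    def row(self, consonant: str) -> np.ndarray:
        return self.counts[self.presented_labels.index(consonant)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.counts,
            index=list(self.presented_labels),
            columns=list(self.response_labels),
        )


def assign_category(pta_db_hl: float) -> str:
    """Assign the hearing category for a 3-frequency PTA in dB HL.

    Non-integer PTAs are rounded half-up before banding, matching the
    integer-dB convention of audiometric reporting.
    """
    if not math.isfinite(pta_db_hl):
        raise ValueError("PTA must be finite")
    pta = math.floor(pta_db_hl + 0.5)
    if pta > PTA_MAX:
        raise ValueError(f"PTA {pta_db_hl} dB HL exceeds inclusion limit ({PTA_MAX})")
    if pta < PTA_MIN:
        raise ValueError(f"PTA {pta_db_hl} dB HL below measurable range ({PTA_MIN})")
    for name, (lo, hi) in CATEGORY_BANDS.items():
        if lo <= pta <= hi:
            return name
    raise AssertionError("category bands do not cover the PTA range")


def build_confusion_matrix(
    trials: Iterable[TrialRecord],
    *,
    presented_labels: Sequence[str] | None = None,
    response_labels: Sequence[str] | None = None,
    where: Callable[[TrialRecord], bool] | None = None,
    snr_db: float | None = None,
    block: int | None = None,
    aided: str | None = None,
    session_id: str | None = None,
) -> ConfusionMatrix:
    """Tally trials into a confusion matrix after optional filtering.

    All selected trials must come from a single listener and a single aided
    condition.  Responses outside ``response_labels`` (off-panel buttons when
    tallying against a reduced panel) are mapped to OTHER.
    """
    selected = [
        t
        for t in trials
        if (where is None or where(t))
        and (snr_db is None or t.snr_db == snr_db)
        and (block is None or t.block == block)
        and (aided is None or t.aided == aided)
        and (session_id is None or t.session_id == session_id)
    ]
    if not selected:
        raise ValueError("empty selection: no trials to tally")
    listeners = {t.listener_id for t in selected}
    if len(listeners) > 1:
        raise ValueError(f"mixed listeners in selection: {sorted(listeners)}")
    conditions = {t.aided for t in selected}
    if len(conditions) > 1:
        raise ValueError(
            f"mixed aided conditions in selection: {sorted(conditions)}; "
            "pass aided=... to filter"
        )

    if presented_labels is None:
        presented_labels = tuple(c for c in CONSONANTS if any(t.consonant == c for t in selected))
    else:
        presented_labels = tuple(presented_labels)
    if response_labels is None:
        response_labels = presented_labels + (OTHER,)
    else:
        response_labels = tuple(response_labels)
    if OTHER not in response_labels:
        raise ValueError("response_labels must include OTHER")

    pres_index = {c: i for i, c in enumerate(presented_labels)}
    resp_index = {c: j for j, c in enumerate(response_labels)}
    counts = np.zeros((len(presented_labels), len(response_labels)), dtype=int)
    for t in selected:
        if t.consonant not in pres_index:
            raise ValueError(
                f"trial consonant {t.consonant!r} not in presented_labels"
            )
        j = resp_index.get(t.response, resp_index[OTHER])
        counts[pres_index[t.consonant], j] += 1
    return ConfusionMatrix(
        presented_labels=presented_labels,
        response_labels=response_labels,
        counts=counts,
        listener_id=selected[0].listener_id,
        aided=selected[0].aided,
    )


def score_percent_correct(cm: ConfusionMatrix) -> float:
    """Percent correct: 100 x (sum of diagonal counts) / n_trials.

    The diagonal pairs each presented consonant with the response of the
    same label; the OTHER column has no diagonal cell and never contributes.
    """
    if cm.n_trials < 1:
        raise ValueError("no trials")
    diag = sum(
        cm.counts[i, cm.response_labels.index(c)]
        for i, c in enumerate(cm.presented_labels)
        if c in cm.response_labels
    )
    return 100.0 * diag / cm.n_trials
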