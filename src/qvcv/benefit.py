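"""Hearing-aid benefit from aided-vs-unaided test scores.

Benefit is expressed both as the percent-correct improvement and as the
reduction in predicted hearing loss in dB (unaided PPTA minus aided PPTA;
positive means the aid helped).  A dB benefit is called significant only
when it exceeds the test's own test-retest repeatability limit (5 dB),
since smaller differences are indistinguishable from measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConfusionMatrix, ListenerMeta, score_percent_correct
from .pta_model import PtaModel, predict_ppta, vectorize_ccm
from .reliability import quicksin_reference

#: Aided scores at or above this are "restored to the normal-hearing ceiling".
NH_CEILING_PERCENT = 90.0


@dataclass(frozen=True)
class BenefitResult:
    listener_id: str
    condition_pair: tuple[str, str]
    unaided_percent: float
    aided_percent: float
    delta_percent: float
    unaided_ppta_db: float
    aided_ppta_db: float
    delta_db: float
    significant: bool
    at_nh_ceiling: bool


def hearing_aid_benefit(
    unaided_cm: ConfusionMatrix,
    aided_cm: ConfusionMatrix,
    model: PtaModel,
    repeatability_limit_db: float | None = None,
) -> BenefitResult:
    """Per-listener benefit: score and PPTA deltas with a significance flag.

    delta_percent = aided - unaided score; delta_db = unaided PPTA - aided
    PPTA (positive = benefit); significant iff delta_db strictly exceeds the
    repeatability limit.
    """
    if unaided_cm.listener_id != aided_cm.listener_id:
        raise ValueError(
            f"mismatched listeners: {unaided_cm.listener_id!r} vs "
            f"{aided_cm.listener_id!r}"
        )
    if repeatability_limit_db is None:
        repeatability_limit_db = quicksin_reference()["qvcv_repeatability_db"]
    u_pct = score_percent_correct(unaided_cm)
    a_pct = score_percent_correct(aided_cm)
    u_db = predict_ppta(model, vectorize_ccm(unaided_cm))
    a_db = predict_ppta(model, vectorize_ccm(aided_cm))
    delta_db = u_db - a_db
    return BenefitResult(
        listener_id=unaided_cm.listener_id,
        condition_pair=(unaided_cm.aided, aided_cm.aided),
        unaided_percent=u_pct,
        aided_percent=a_pct,
        delta_percent=a_pct - u_pct,
        unaided_ppta_db=u_db,
        aided_ppta_db=a_db,
        delta_db=delta_db,
        significant=delta_db > repeatability_limit_db,
        at_nh_ceiling=a_pct > NH_CEILING_PERCENT,
    )


def benefit_report(
    results: Sequence[BenefitResult],
    meta: Mapping[str, ListenerMeta] | Sequence[ListenerMeta] | None = None,
) -> pd.DataFrame:
    """Cohort summary: per-category counts of significant benefit and mean
    deltas, plus how many aided scores reach the normal-hearing ceiling."""
    if not results:
        raise ValueError("no benefit results")
    if meta is not None and not isinstance(meta, Mapping):
        meta = {m.listener_id: m for m in meta}
    rows = []
    for r in results:
        cat = pta = None
        if meta is not None and r.listener_id in meta:
            cat = meta[r.listener_id].category
            pta = meta[r.listener_id].measured_pta_db_hl
        rows.append(
            {
                "listener_id": r.listener_id,
                "category": cat or "unknown",
                "measured_pta_db_hl": pta,
                "delta_percent": r.delta_percent,
                "delta_db": r.delta_db,
                "significant": r.significant,
                "at_nh_ceiling": r.at_nh_ceiling,
            }
        )
    per = pd.DataFrame(rows)
    summary = (
        per.groupby("category")
        .agg(
            n=("listener_id", "count"),
            n_significant=("significant", "sum"),
            mean_delta_percent=("delta_percent", "mean"),
            mean_delta_db=("delta_db", "mean"),
            mean_pta=("measured_pta_db_hl", "mean"),
            n_at_ceiling=("at_nh_ceiling", "sum"),
        )
        .reset_index()
    )
    return summary
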