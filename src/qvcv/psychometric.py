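"""Per-token psychometric functions and SNR90 extrapolation.

Performance on each VCV token is measured at a few fixed SNRs and a
logistic psychometric function with a guess floor and a lapse ceiling,

    P(s) = gamma + (1 - gamma - lapse) * sigma(beta * (s - m)),

is fitted by penalized maximum likelihood.  The SNR at which the fitted
curve crosses 90% correct (SNR90) is then solved analytically; tokens whose
curves never cross 90% within a bounded extrapolation window are flagged
rather than assigned a number.  gamma defaults to 1/14, the reciprocal of
the number of response buttons in the closed set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

DEFAULT_GUESS = 1.0 / 14.0
DEFAULT_LAPSE = 0.02

#: How far (dB) beyond the observed SNR range an SNR90 may be extrapolated.
EXTRAPOLATION_CAP_DB = 6.0

# Flags for tokens whose SNR90 is not a usable number.
SATURATED = "SATURATED"    # above 90% already at the lowest tested SNR
UNREACHED = "UNREACHED"    # below 90% beyond the extrapolation window
DEGENERATE = "DEGENERATE"  # data carry no slope information

# Weak Gaussian prior on log(slope), centred on 1 /dB.  It only matters for
# near-degenerate 2-3 point fits, where it keeps the slope finite.
_LOG_BETA_PRIOR_MEAN = 0.0
_LOG_BETA_PRIOR_SD = 3.0


@dataclass
class PsychometricFit:
    """Fitted performance-vs-SNR curve for one token."""

    token: tuple[str, str]
    snr_points: list[tuple[float, int, int]]  # (snr_db, n_trials, n_correct)
    guess_rate: float
    midpoint_db: float
    slope_per_db: float
    lapse: float
    degenerate: bool = False

    def predict(self, snr_db) -> np.ndarray:
        """Fitted proportion correct at the given SNR(s)."""
        s = np.asarray(snr_db, dtype=float)
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse) * expit(
            self.slope_per_db * (s - self.midpoint_db)
        )

    @property
    def snr90_db(self) -> float | str:
        return snr90(self)


def _neg_log_posterior(params, snrs, n, k, gamma, lapse):
    m, log_beta = params
    beta = math.exp(log_beta)
    p = gamma + (1.0 - gamma - lapse) * expit(beta * (snrs - m))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    nll = -np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p))
    prior = 0.5 * ((log_beta - _LOG_BETA_PRIOR_MEAN) / _LOG_BETA_PRIOR_SD) ** 2
    return nll + prior


def fit_psychometric(
    points: Iterable[tuple[float, int, int]],
    guess_rate: float = DEFAULT_GUESS,
    lapse: float = DEFAULT_LAPSE,
    token: tuple[str, str] = ("", ""),
) -> PsychometricFit:
    """Fit the logistic psychometric function by penalized ML.

    ``points`` is an iterable of ``(snr_db, n_trials, n_correct)``.  The fit
    is deterministic: a coarse grid over (midpoint, log-slope) seeds a
    Nelder-Mead refinement.  All-correct or all-wrong data at every SNR are
    flagged degenerate with parameters pinned at bounds.
    """
    pts = sorted((float(s), int(n), int(k)) for s, n, k in points)
    if len({s for s, _, _ in pts}) < 2:
        raise ValueError("need >= 2 distinct SNRs")
    if any(n < 1 or k < 0 or k > n for _, n, k in pts):
        raise ValueError("invalid counts")
    if not 0.0 <= guess_rate < 1.0:
        raise ValueError("guess_rate must be in [0, 1)")
    snrs = np.array([s for s, _, _ in pts])
    n = np.array([nn for _, nn, _ in pts])
    k = np.array([kk for _, _, kk in pts])

    if (k == n).all() or (k == 0).all():
        # No crossing information: pin the midpoint outside the tested range.
        mid = snrs.min() - 1.0 if (k == n).all() else snrs.max() + 1.0
        return PsychometricFit(
            token=token, snr_points=pts, guess_rate=guess_rate,
            midpoint_db=mid, slope_per_db=10.0, lapse=lapse, degenerate=True,
        )

    span = snrs.max() - snrs.min()
    m_grid = np.linspace(snrs.min() - 2 * span, snrs.max() + 2 * span, 81)
    lb_grid = np.linspace(math.log(0.02), math.log(10.0), 41)
    best = None
    for m0 in m_grid:
        for lb0 in lb_grid:
            v = _neg_log_posterior((m0, lb0), snrs, n, k, guess_rate, lapse)
            if best is None or v < best[0]:
                best = (v, m0, lb0)
    res = minimize(
        _neg_log_posterior,
        x0=[best[1], best[2]],
        args=(snrs, n, k, guess_rate, lapse),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
    )
    m_hat, log_beta_hat = res.x
    return PsychometricFit(
        token=token,
        snr_points=pts,
        guess_rate=guess_rate,
        midpoint_db=float(m_hat),
        slope_per_db=float(math.exp(log_beta_hat)),
        lapse=lapse,
    )


def snr90(fit: PsychometricFit, target: float = 0.90) -> float | str:
    """Solve the fitted curve for the SNR giving ``target`` proportion correct.

    Returns SATURATED when the curve already exceeds the target at the lowest
    tested SNR, UNREACHED when it stays below the target more than
    ``EXTRAPOLATION_CAP_DB`` beyond the highest tested SNR, and DEGENERATE
    when the fit carried no slope information.
    """
    if fit.degenerate:
        ks = [k for _, _, k in fit.snr_points]
        ns = [n for _, n, _ in fit.snr_points]
        if ks == ns:  # all correct everywhere
            return SATURATED
        return DEGENERATE
    snrs = [s for s, _, _ in fit.snr_points]
    ceiling = 1.0 - fit.lapse
    if target >= ceiling:
        return UNREACHED
    if target <= fit.guess_rate:
        return SATURATED
    if fit.predict(min(snrs)) > target:
        return SATURATED
    q = (target - fit.guess_rate) / (1.0 - fit.guess_rate - fit.lapse)
    s90 = fit.midpoint_db + logit(q) / fit.slope_per_db
    if fit.predict(max(snrs)) < target and s90 > max(snrs) + EXTRAPOLATION_CAP_DB:
        return UNREACHED
    if s90 < min(snrs) - EXTRAPOLATION_CAP_DB:
        return SATURATED
    return float(s90)


def propose_snr_grid(fit: PsychometricFit, step_db: float = 3.0) -> tuple[int, int, int]:
    """Propose the narrowed {SNR90-3, SNR90, SNR90+3} grid, integer dB."""
    s90 = snr90(fit)
    if isinstance(s90, str):
        raise ValueError(f"SNR90 not defined for this fit ({s90})")
    center = int(math.floor(s90 + 0.5))
    return (int(center - step_db), center, int(center + step_db))


def fit_report(fits: Sequence[PsychometricFit]):
    """Tabulate fits as a DataFrame (consonant, vowel, m, slope, snr90)."""
    import pandas as pd

    rows = []
    for f in fits:
        s90 = snr90(f)
        rows.append(
            {
                "consonant": f.token[0],
                "vowel": f.token[1],
                "midpoint_db": f.midpoint_db,
                "slope_per_db": f.slope_per_db,
                "guess_rate": f.guess_rate,
                "lapse": f.lapse,
                "snr90_db": s90 if isinstance(s90, float) else math.nan,
                "flag": s90 if isinstance(s90, str) else "OK",
            }
        )
    return pd.DataFrame(rows)
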