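"""Synthetic listeners for exercising the test pipeline end to end.

The generator produces trial-level responses with the statistical structure
the analyses assume: percent correct declines monotonically with hearing
loss, normal-hearing listeners sit near 90% at the calibrated panel SNRs,
errors fall on phonetically similar consonants, and a designated subgroup
carries "excess loss" — perceptual deficit beyond what their audiogram
(true PTA) shows.

Response model.  Each token has a logistic psychometric function in SNR
whose midpoint shifts to the right as the listener's *effective* loss rises
above a 15 dB HL knee:

    P(correct) = g + (1 - g - lapse) *
                 sigma(slope * (snr - midpoint - loss_shift * max(0, L - 15)))

with effective loss L = true PTA + excess offset - aided relief (floored at
-10 dB HL).  Wrong responses are drawn from a confusion kernel built from
voicing/manner/place feature distances, so /s/ is misheard as /ʃ/ far more
often than as /m/.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .core import (
    CONSONANTS,
    OTHER,
    CATEGORY_BANDS,
    CATEGORIES,
    ListenerMeta,
    TrialRecord,
)
from .psychometric import DEFAULT_GUESS, DEFAULT_LAPSE
from .token_selection import TokenPanel, PanelEntry

LOSS_KNEE_DB_HL = 15.0
EFFECTIVE_LOSS_FLOOR = -10.0

# Documented simulator constants.  Slopes are consonant-in-noise
# psychometric slopes (~6-10 percentage points per dB near the midpoint),
# drawn per token from a seeded range.
#
# The loss-to-SNR-deficit map is compressive (two segments): effective loss
# just above the knee costs the most SNR per dB HL (near rate), and deeper
# losses accrue deficit at a shallower rate — suprathreshold speech-in-noise
# deficits grow fastest at the onset of loss and saturate, which is also
# what keeps deep losses off the guess floor and hence still informative.
# Where a token carries a published discriminability AUC, the near rate is
# calibrated to reproduce that AUC (see ``calibrate_token_models``);
# otherwise both rates are drawn from the fallback ranges.
SLOPE_RANGE_PER_DB = (0.25, 0.45)
# Fallback near-knee rates (used only for tokens without an AUC anchor,
# i.e. screening-mode candidates) put an informative consonant's expected
# screening AUC in the 0.93-0.99 band where retained consonants sit.
NEAR_LOSS_RATE_RANGE = (0.90, 1.40)   # dB SNR per dB HL, first segment
DEEP_LOSS_RATE_RANGE = (0.20, 0.30)   # dB SNR per dB HL, beyond breakpoint
                                      # (clinical SNR-loss growth rates)
SHIFT_BREAKPOINT_DB = 10.0            # dB HL above the knee where rate drops
NEAR_LOSS_RATE_MAX = 3.0
KERNEL_TEMPERATURE = 1.0
OTHER_FEATURE_DISTANCE = 2.5
#: The confusion pattern itself degrades with loss: place-of-articulation
#: cues (carried by high-frequency detail) fade first, so the error kernel
#: interpolates from the full-feature similarity kernel toward a
#: place-blind kernel as effective loss rises over this span (dB HL above
#: the knee).
DEEP_KERNEL_SPAN_DB = 30.0
OTHER_FEATURE_DISTANCE_DEEP = 1.0

#: Reference composition used when calibrating a token's deficit rates to
#: its published AUC: equal thirds of slight/mild/moderate losses, and the
#: screening experiment's per-token trial count (2 recordings x 3 SNRs x 10
#: presentations = 60 trials per listener per consonant-vowel token).
AUC_CALIBRATION_TRIALS = 60

#: Per-vowel noise settings used by the screening-mode cohorts only: /ɑ/ is
#: the most consistent context, /i/ noisier, /u/ noisiest (and largely
#: redundant).  Jitter is listener-by-token midpoint scatter; the offset is
#: a listener-by-vowel shift (a listener's idiosyncratic difficulty with a
#: vowel context, shared by all its tokens) — it is the offset that dilutes
#: a vowel's group-separation AUC.  The single-vowel test cohorts use the
#: bare response model, where individual differences enter only through
#: PTA, excess offset and lapse.
VOWEL_JITTER_SD_DB = {"ɑ": 1.0, "i": 2.5, "u": 4.0}
VOWEL_OFFSET_SD_DB = {"ɑ": 0.5, "i": 2.0, "u": 4.0}

# Phonetic features (voicing, manner, place) for the 13 consonants.
_FEATURES = {
    "b": (1, "stop", "bilabial"),
    "p": (0, "stop", "bilabial"),
    "d": (1, "stop", "alveolar"),
    "t": (0, "stop", "alveolar"),
    "g": (1, "stop", "velar"),
    "k": (0, "stop", "velar"),
    "v": (1, "fricative", "labiodental"),
    "f": (0, "fricative", "labiodental"),
    "z": (1, "fricative", "alveolar"),
    "s": (0, "fricative", "alveolar"),
    "ʃ": (0, "fricative", "postalveolar"),
    "m": (1, "nasal", "bilabial"),
    "n": (1, "nasal", "alveolar"),
}


def feature_distance(c1: str, c2: str) -> int:
    """Hamming distance over (voicing, manner, place)."""
    f1, f2 = _FEATURES[c1], _FEATURES[c2]
    return sum(a != b for a, b in zip(f1, f2))


@dataclass(frozen=True)
class ListenerProfile:
    """Simulator ground truth for one listener."""

    listener_id: str
    true_pta_db_hl: float
    excess_offset_db: float = 0.0
    lapse: float = DEFAULT_LAPSE
    guess_floor: float = DEFAULT_GUESS
    aided_relief_db: float = 0.0

    def __post_init__(self) -> None:
        if not -10.0 <= self.true_pta_db_hl <= 55.0:
            raise ValueError("true PTA outside [-10, 55] dB HL")
        if self.excess_offset_db < 0 or self.aided_relief_db < 0:
            raise ValueError("offsets must be >= 0")
        if not (0 <= self.lapse < 1 and 0 <= self.guess_floor < 1):
            raise ValueError("probabilities must be in [0, 1)")

    def effective_loss(self, aided: bool = False) -> float:
        loss = self.true_pta_db_hl + self.excess_offset_db
        if aided:
            loss -= self.aided_relief_db
        return max(EFFECTIVE_LOSS_FLOOR, loss)


@dataclass
class TokenModel:
    """Generative psychometric model for one (consonant, vowel) token.

    ``loss_shift_per_db`` is the near-knee rate of the compressive
    loss-to-SNR-deficit map; beyond ``shift_breakpoint_db`` dB HL above the
    knee the deficit accrues at ``deep_loss_shift_per_db`` instead.
    """

    token: tuple[str, str]
    midpoint_db: float
    slope_per_db: float
    loss_shift_per_db: float
    confusion_kernel: dict[str, float]  # wrong response -> probability
    deep_loss_shift_per_db: float | None = None
    shift_breakpoint_db: float = SHIFT_BREAKPOINT_DB
    deep_confusion_kernel: dict[str, float] | None = None
    jitter_sd_db: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_per_db <= 0:
            raise ValueError("slope must be > 0")
        if self.loss_shift_per_db < 0:
            raise ValueError("loss_shift must be >= 0")
        if self.deep_loss_shift_per_db is None:
            self.deep_loss_shift_per_db = self.loss_shift_per_db
        if self.deep_loss_shift_per_db < 0:
            raise ValueError("deep loss_shift must be >= 0")
        if self.deep_confusion_kernel is None:
            self.deep_confusion_kernel = dict(self.confusion_kernel)
        for kernel in (self.confusion_kernel, self.deep_confusion_kernel):
            if not math.isclose(sum(kernel.values()), 1.0, abs_tol=1e-9):
                raise ValueError("confusion kernel must sum to 1")

    def snr_deficit(self, effective_loss: float) -> float:
        """dB of SNR deficit for a given effective loss (dB HL)."""
        x = max(0.0, effective_loss - LOSS_KNEE_DB_HL)
        near = min(x, self.shift_breakpoint_db)
        deep = max(0.0, x - self.shift_breakpoint_db)
        return self.loss_shift_per_db * near + self.deep_loss_shift_per_db * deep

    def p_correct(
        self,
        snr_db: float,
        effective_loss: float,
        guess: float = DEFAULT_GUESS,
        lapse: float = DEFAULT_LAPSE,
        midpoint_jitter_db: float = 0.0,
    ) -> float:
        x = self.slope_per_db * (
            snr_db - self.midpoint_db - midpoint_jitter_db
            - self.snr_deficit(effective_loss)
        )
        return guess + (1.0 - guess - lapse) * expit(x)

    def error_kernel(self, effective_loss: float) -> dict[str, float]:
        """Wrong-response distribution at a given effective loss.

        Interpolates from the full-feature kernel toward the place-blind
        deep kernel as loss rises above the knee.
        """
        w = min(1.0, max(0.0, effective_loss - LOSS_KNEE_DB_HL) / DEEP_KERNEL_SPAN_DB)
        if w == 0.0 or self.deep_confusion_kernel == self.confusion_kernel:
            return self.confusion_kernel
        return {
            r: (1.0 - w) * p + w * self.deep_confusion_kernel[r]
            for r, p in self.confusion_kernel.items()
        }


def make_confusion_kernel(
    consonant: str,
    response_set: Sequence[str],
    temperature: float = KERNEL_TEMPERATURE,
) -> dict[str, float]:
    """Softmax-over-similarity kernel over the wrong responses.

    Probability of mishearing ``consonant`` as r is proportional to
    exp(-d(consonant, r)/T) with d the phonetic-feature Hamming distance;
    OTHER sits at a fixed pseudo-distance.  T -> inf gives a uniform kernel.
    """
    wrong = [r for r in response_set if r != consonant]
    if not wrong:
        raise ValueError("response set leaves no wrong responses")
    d = np.array(
        [
            OTHER_FEATURE_DISTANCE if r == OTHER else feature_distance(consonant, r)
            for r in wrong
        ],
        dtype=float,
    )
    w = np.exp(-d / temperature)
    w /= w.sum()
    return dict(zip(wrong, w))


def make_deep_confusion_kernel(
    consonant: str,
    response_set: Sequence[str],
    temperature: float = KERNEL_TEMPERATURE,
) -> dict[str, float]:
    """Error kernel for severely reduced audibility: place cues are lost.

    Distance counts only voicing and manner mismatches, so errors spread
    over same-manner consonants regardless of place, and the OTHER button
    sits closer (listeners report hearing something not in the set more
    often when the signal is badly degraded).
    """
    wrong = [r for r in response_set if r != consonant]
    if not wrong:
        raise ValueError("response set leaves no wrong responses")
    f0 = _FEATURES[consonant]
    d = np.array(
        [
            OTHER_FEATURE_DISTANCE_DEEP
            if r == OTHER
            else sum(a != b for a, b in zip(f0[:2], _FEATURES[r][:2]))
            for r in wrong
        ],
        dtype=float,
    )
    w = np.exp(-d / temperature)
    w /= w.sum()
    return dict(zip(wrong, w))


def _token_auc_for_rates(
    near_rate: float,
    deep_rate: float,
    slope: float,
    snr_db: float,
    midpoint_db: float,
    guess: float,
    lapse: float,
    breakpoint_db: float = SHIFT_BREAKPOINT_DB,
    n_trials: int = AUC_CALIBRATION_TRIALS,
) -> float:
    """Expected per-token NH-vs-HL Mann-Whitney AUC for given deficit rates.

    Per-listener scores are binomial proportions over ``n_trials``; normal
    hearing sits at the calibrated probability, hearing loss integrates over
    the slight/mild/moderate bands in equal thirds.
    """
    from scipy.stats import binom

    span = 1.0 - guess - lapse
    p_nh = guess + span * expit(slope * (snr_db - midpoint_db))
    k = np.arange(n_trials + 1)
    pmf_nh = binom.pmf(k, n_trials, p_nh)
    ptas = np.concatenate(
        [np.arange(16, 26), np.arange(26, 41), np.arange(41, 56)]
    ).astype(float)
    w = np.concatenate(
        [np.full(10, 1 / 30), np.full(15, 1 / 45), np.full(15, 1 / 45)]
    )
    x = ptas - LOSS_KNEE_DB_HL
    deficit = near_rate * np.minimum(x, breakpoint_db) + deep_rate * np.maximum(
        0.0, x - breakpoint_db
    )
    p_hl = guess + span * expit(slope * (snr_db - midpoint_db - deficit))
    auc = 0.0
    for p, wt in zip(p_hl, w):
        cdf_hl = binom.cdf(k, n_trials, p)
        pmf_hl = binom.pmf(k, n_trials, p)
        win = np.sum(pmf_nh[1:] * cdf_hl[:-1]) + 0.5 * np.sum(pmf_nh * pmf_hl)
        auc += wt * win
    return float(auc)


def _calibrate_near_rate(
    target_auc: float,
    deep_rate: float,
    slope: float,
    snr_db: float,
    midpoint_db: float,
    guess: float,
    lapse: float,
) -> float:
    """Solve for the near-knee rate whose expected token AUC hits the target."""
    from scipy.optimize import brentq

    def f(c):
        return (
            _token_auc_for_rates(c, deep_rate, slope, snr_db, midpoint_db, guess, lapse)
            - target_auc
        )

    if f(NEAR_LOSS_RATE_MAX) <= 0:  # target at/above the reachable ceiling
        return NEAR_LOSS_RATE_MAX
    if f(0.0) >= 0:  # deep-rate separation alone already suffices
        return 0.0
    return float(brentq(f, 0.0, NEAR_LOSS_RATE_MAX, xtol=1e-4))


def calibrate_token_models(
    panel: TokenPanel,
    target_nh_score: float = 0.90,
    rng: np.random.Generator | int | None = 0,
    guess: float = DEFAULT_GUESS,
    lapse: float = DEFAULT_LAPSE,
    temperature: float = KERNEL_TEMPERATURE,
    vowel_jitter_sd_db: Mapping[str, float] | None = None,
) -> dict[tuple[str, str], TokenModel]:
    """Set token midpoints so listeners at the loss knee score the target.

    For each panel token the midpoint is chosen so the closed-form
    P(correct) at the token's panel SNR equals ``target_nh_score`` for
    effective loss at (or below) the 15 dB HL knee.  Slopes and deep-loss
    deficit rates are drawn from the documented seeded ranges.  The
    near-knee deficit rate is calibrated so each token reproduces its
    panel-entry discriminability AUC on the reference cohort composition
    (tokens without a meaningful AUC anchor, e.g. screening-mode
    placeholders, draw from the documented fallback range instead).
    Kernels come from phonetic similarity.  ``vowel_jitter_sd_db``
    (screening mode) attaches per-vowel listener-by-token midpoint jitter;
    by default tokens carry none.
    """
    if not guess < target_nh_score < 1.0 - lapse:
        raise ValueError(
            f"target {target_nh_score} unreachable with guess {guess} "
            f"and lapse {lapse}"
        )
    rng = np.random.default_rng(rng)
    jitter = dict(vowel_jitter_sd_db) if vowel_jitter_sd_db else {}
    q = logit((target_nh_score - guess) / (1.0 - guess - lapse))
    models = {}
    # Intrinsic consonant parameters are shared across vowel contexts, so a
    # multi-vowel screening panel differs between vowels only through the
    # designed per-vowel noise settings, not draw luck.
    per_consonant: dict[str, tuple[float, float, float]] = {}
    for entry in panel.entries:
        if entry.consonant not in per_consonant:
            per_consonant[entry.consonant] = (
                rng.uniform(*SLOPE_RANGE_PER_DB),
                rng.uniform(*NEAR_LOSS_RATE_RANGE),
                rng.uniform(*DEEP_LOSS_RATE_RANGE),
            )
        slope, fallback_near, deep_rate = per_consonant[entry.consonant]
        midpoint = entry.snr_db - q / slope
        if entry.auc > 0.55:
            near_rate = _calibrate_near_rate(
                entry.auc, deep_rate, slope, entry.snr_db, midpoint, guess, lapse
            )
        else:
            near_rate = fallback_near
        models[(entry.consonant, entry.vowel)] = TokenModel(
            token=(entry.consonant, entry.vowel),
            midpoint_db=midpoint,
            slope_per_db=slope,
            loss_shift_per_db=near_rate,
            deep_loss_shift_per_db=deep_rate,
            confusion_kernel=make_confusion_kernel(
                entry.consonant, panel.response_set, temperature
            ),
            deep_confusion_kernel=make_deep_confusion_kernel(
                entry.consonant, panel.response_set, temperature
            ),
            jitter_sd_db=jitter.get(entry.vowel, 0.0),
        )
    return models


def simulate_trial(
    profile: ListenerProfile,
    token_model: TokenModel,
    snr_db: float,
    rng: np.random.Generator,
    aided: str = "unaided",
    session_id: str = "s1",
    block: int = 1,
    recording: int = 1,
    midpoint_jitter_db: float = 0.0,
) -> TrialRecord:
    """Draw one trial: correct with the closed-form probability, else a
    confusion-kernel response."""
    eff = profile.effective_loss(aided=aided != "unaided")
    p = token_model.p_correct(
        snr_db,
        eff,
        guess=profile.guess_floor,
        lapse=profile.lapse,
        midpoint_jitter_db=midpoint_jitter_db,
    )
    consonant, vowel = token_model.token
    if rng.random() < p:
        response = consonant
    else:
        kernel = token_model.error_kernel(eff)
        wrong = list(kernel)
        probs = np.array([kernel[r] for r in wrong])
        response = wrong[rng.choice(len(wrong), p=probs)]
    return TrialRecord(
        listener_id=profile.listener_id,
        session_id=session_id,
        block=block,
        consonant=consonant,
        vowel=vowel,
        recording=recording,
        snr_db=snr_db,
        response=response,
        aided=aided,
    )


def simulate_session(
    profile: ListenerProfile,
    token_models: Mapping[tuple[str, str], TokenModel],
    panel: TokenPanel,
    rng: np.random.Generator,
    trials_per_token: int = 5,
    session_id: str = "s1",
    aided: str = "unaided",
    trials_per_block: int = 100,
    jitter: Mapping[tuple[str, str], float] | None = None,
) -> list[TrialRecord]:
    """One balanced session: each (token, recording) x trials_per_token,
    shuffled, then numbered into blocks."""
    plan = [
        (entry, rec)
        for entry in panel.entries
        for rec in (1, 2)
        for _ in range(trials_per_token)
    ]
    order = rng.permutation(len(plan))
    trials = []
    for pos, idx in enumerate(order):
        entry, rec = plan[idx]
        tm = token_models[(entry.consonant, entry.vowel)]
        trials.append(
            simulate_trial(
                profile,
                tm,
                float(entry.snr_db),
                rng,
                aided=aided,
                session_id=session_id,
                block=1 + pos // trials_per_block,
                recording=rec,
                midpoint_jitter_db=(
                    jitter.get((entry.consonant, entry.vowel), 0.0) if jitter else 0.0
                ),
            )
        )
    return trials


def simulate_cohort(
    n_per_category: Mapping[str, int] | Sequence[int] | int = 15,
    panel: TokenPanel | None = None,
    trials_per_token: int = 5,
    n_sessions: int = 2,
    excess_fraction: float = 0.0,
    excess_delta_db: float = 10.0,
    excess_categories: Sequence[str] = ("slight", "mild", "moderate"),
    aided_conditions: Sequence[str] = ("unaided",),
    aided_relief_db: float = 0.0,
    target_nh_score: float = 0.90,
    seed: int = 0,
) -> tuple[list[TrialRecord], list[ListenerMeta], list[ListenerProfile]]:
    """Simulate a cohort of listeners with balanced sessions.

    True PTAs are drawn uniformly within each category band.  A fraction of
    listeners (rounded to the nearest count, drawn from ``excess_categories``
    — categories whose loss is above the knee, so the injected offset is an
    observable ground truth) receive ``excess_delta_db`` of excess loss.
    Token models are calibrated so that listeners at or below the knee score
    ``target_nh_score`` at the panel SNRs.
    """
    from .token_selection import packaged_default_panel

    if panel is None:
        panel = packaged_default_panel()
    if isinstance(n_per_category, int):
        n_per_category = {c: n_per_category for c in CATEGORIES}
    elif not isinstance(n_per_category, Mapping):
        n_per_category = dict(zip(CATEGORIES, n_per_category))

    rng = np.random.default_rng(seed)
    token_models = calibrate_token_models(panel, target_nh_score, rng)

    profiles: list[ListenerProfile] = []
    metas: list[ListenerMeta] = []
    i = 0
    for cat in CATEGORIES:
        lo, hi = CATEGORY_BANDS[cat]
        for _ in range(n_per_category.get(cat, 0)):
            pta = round(float(rng.uniform(lo, hi)))
            pta = min(max(pta, lo), hi)
            profiles.append(
                ListenerProfile(
                    listener_id=f"L{i:03d}",
                    true_pta_db_hl=pta,
                    aided_relief_db=aided_relief_db,
                )
            )
            metas.append(ListenerMeta(listener_id=f"L{i:03d}", measured_pta_db_hl=pta))
            i += 1

    n_total = len(profiles)
    n_excess = int(round(excess_fraction * n_total))
    if n_excess > 0:
        eligible = [
            j for j, m in enumerate(metas) if m.category in excess_categories
        ]
        if n_excess > len(eligible):
            raise ValueError("not enough eligible listeners for excess fraction")
        chosen = rng.choice(eligible, size=n_excess, replace=False)
        for j in chosen:
            p = profiles[j]
            profiles[j] = ListenerProfile(
                listener_id=p.listener_id,
                true_pta_db_hl=p.true_pta_db_hl,
                excess_offset_db=excess_delta_db,
                lapse=p.lapse,
                guess_floor=p.guess_floor,
                aided_relief_db=p.aided_relief_db,
            )

    trials: list[TrialRecord] = []
    for profile in profiles:
        for aided in aided_conditions:
            for s in range(1, n_sessions + 1):
                sid = f"s{s}" if aided == "unaided" else f"s{s}-{aided}"
                trials.extend(
                    simulate_session(
                        profile,
                        token_models,
                        panel,
                        rng,
                        trials_per_token=trials_per_token,
                        session_id=sid,
                        aided=aided,
                    )
                )
    return trials, metas, profiles


def selection_panel(
    consonants: Sequence[str] = CONSONANTS,
    vowels: Sequence[str] = ("ɑ", "i"),
    snrs: Sequence[int] = (0,),
) -> TokenPanel:
    """A screening-phase panel: all candidate consonants x vowel contexts.

    Only single-SNR panels are representable per token; screening over
    several SNRs is done by simulating one panel per SNR.
    """
    return TokenPanel(
        entries=tuple(
            PanelEntry(c, v, int(s), 0.5)
            for v in vowels
            for c in consonants
            for s in snrs[:1]
        )
    )


def simulate_selection_cohort(
    n_per_category: int = 15,
    uninformative: Sequence[str] = ("f", "m", "p"),
    vowels: Sequence[str] = ("ɑ", "i"),
    trials_per_token: int = 10,
    seed: int = 0,
) -> tuple[list[TrialRecord], list[ListenerMeta], list[ListenerProfile]]:
    """A screening-phase cohort where some consonants carry no loss signal.

    All 13 consonants are presented in the given vowel contexts; the
    ``uninformative`` consonants get loss_shift = 0 so their scores do not
    separate normal hearing from hearing loss, and /i/ carries more
    listener-by-token variability than /ɑ/.
    """
    panel = selection_panel(vowels=vowels)
    rng = np.random.default_rng(seed)
    token_models = calibrate_token_models(
        panel, rng=rng, vowel_jitter_sd_db=VOWEL_JITTER_SD_DB
    )
    for key, tm in token_models.items():
        if key[0] in uninformative:
            tm.loss_shift_per_db = 0.0
            tm.deep_loss_shift_per_db = 0.0
            tm.deep_confusion_kernel = dict(tm.confusion_kernel)

    profiles: list[ListenerProfile] = []
    metas: list[ListenerMeta] = []
    i = 0
    for cat in CATEGORIES:
        lo, hi = CATEGORY_BANDS[cat]
        for _ in range(n_per_category):
            pta = round(float(rng.uniform(lo, hi)))
            profiles.append(ListenerProfile(f"L{i:03d}", min(max(pta, lo), hi)))
            metas.append(ListenerMeta(f"L{i:03d}", profiles[-1].true_pta_db_hl))
            i += 1
    trials: list[TrialRecord] = []
    for profile in profiles:
        vowel_offset = {v: rng.normal(0.0, VOWEL_OFFSET_SD_DB.get(v, 0.0)) for v in vowels}
        jitter = {
            key: vowel_offset[key[1]] + rng.normal(0.0, tm.jitter_sd_db)
            for key, tm in token_models.items()
        }
        trials.extend(
            simulate_session(
                profile,
                token_models,
                panel,
                rng,
                trials_per_token=trials_per_token,
                session_id="s1",
                jitter=jitter,
            )
        )
    return trials, metas, profiles
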