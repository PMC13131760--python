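"""Prediction of pure-tone-average thresholds from confusion matrices.

The pipeline is: row-normalize and flatten each listener's confusion matrix
into a response-proportion vector, standardize the features, project onto
principal components fitted on the training split, and regress measured PTA
on the component scores with a ridge penalty (lambda = 3 under the
1/2 ||y - Xb||^2 + lambda ||b||^2 convention, intercept unpenalized).
Repeated random 70/30 train/validation splits give each listener a
cross-validated predicted PTA (PPTA).  A piecewise "audibility function"
a(p) = max(floor, p) fitted to the (measured, predicted) pairs provides the
baseline from which residual hearing loss RHL = PPTA - a(PTA) is measured;
RHL above 5 dB flags "excess loss" — perception worse than the audiogram
predicts.  Regularized logistic heads on the same component scores handle
the binary normal-vs-impaired and excess-loss classification tasks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import roc_auc_score

from .core import ConfusionMatrix

DEFAULT_LAMBDA = 3.0
DEFAULT_SPLIT_FRACTION = 0.7
DEFAULT_N_REPEATS = 100
DEFAULT_PCA_VARIANCE = 0.95
DEFAULT_EXCESS_THRESHOLD_DB = 5.0

PPTA_CLIP = (-10.0, 80.0)


# --------------------------------------------------------------------------
# Feature extraction

def vectorize_ccm(cm: ConfusionMatrix) -> np.ndarray:
    """Flatten a confusion matrix into row-normalized response proportions.

    Rows (presented consonants) are normalized to sum to one, then
    concatenated in presented-label order, giving a vector of length
    n_presented * n_response_choices.  Every presented consonant must have
    at least one trial.
    """
    row_sums = cm.counts.sum(axis=1)
    if (row_sums == 0).any():
        empty = [c for c, s in zip(cm.presented_labels, row_sums) if s == 0]
        raise ValueError(f"presented consonants with zero trials: {empty}")
    return (cm.counts / row_sums[:, None]).ravel().astype(float)


def cohort_feature_matrix(
    trials,
    panel,
    aided: str = "unaided",
    session_id: str | None = None,
) -> tuple[list[str], np.ndarray]:
    """Per-listener feature vectors for a cohort of trials.

    Builds one confusion matrix per listener against the panel's consonant
    set (off-panel responses fold into OTHER) and vectorizes it.  Returns
    the sorted listener ids and the (n_listeners, n_features) matrix.
    """
    from .core import build_confusion_matrix

    by_listener: dict[str, list] = {}
    for t in trials:
        by_listener.setdefault(t.listener_id, []).append(t)
    ids = sorted(by_listener)
    X = np.array(
        [
            vectorize_ccm(
                build_confusion_matrix(
                    by_listener[lid],
                    presented_labels=panel.consonants,
                    aided=aided,
                    session_id=session_id,
                )
            )
            for lid in ids
        ]
    )
    return ids, X


# --------------------------------------------------------------------------
# Internal fit of one standardize -> PCA -> ridge (+ logistic) pipeline

class _Pipeline:
    """One fitted standardize->PCA->ridge pipeline (training split only)."""

    def __init__(self, lam: float, pca_variance: float):
        self.lam = lam
        self.pca_variance = pca_variance

    def fit(self, X: np.ndarray, y: np.ndarray | None = None,
            labels: np.ndarray | None = None,
            clf_epv_cap: bool = False) -> "_Pipeline":
        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.x_sd_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.x_mean_) / self.x_sd_

        pca = PCA(n_components=None, svd_solver="full")
        scores = pca.fit_transform(Z)
        ratio = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(ratio, self.pca_variance) + 1)
        k = min(k, scores.shape[1])
        self.components_ = pca.components_[:k]
        self.pca_mean_ = pca.mean_
        scores = scores[:, :k]
        ssd = scores.std(axis=0, ddof=0)
        self.score_sd_ = np.where(ssd > 0, ssd, 1.0)
        S = scores / self.score_sd_

        if y is not None:
            # 1/2||y - Xb||^2 + lam ||b||^2  <=>  ||y - Xb||^2 + 2 lam ||b||^2
            ridge = Ridge(alpha=2.0 * self.lam, fit_intercept=True)
            ridge.fit(S, y)
            self.coef_ = ridge.coef_.copy()
            self.intercept_ = float(ridge.intercept_)
        if labels is not None:
            lab = np.asarray(labels, dtype=int)
            if len(np.unique(lab)) < 2:
                raise ValueError("classifier head needs two classes")
            # Rare-event heads cannot support many covariates: when asked,
            # cap the covariate count by the events-per-variable >= 10 rule
            # (at least one), keeping the leading components — unsupervised
            # selection stays stable where supervised screening on a
            # handful of events would not.
            if clf_epv_cap:
                n_events = int(np.bincount(lab).min())
                idx = np.arange(min(S.shape[1], max(1, n_events // 10)))
            else:
                idx = np.arange(S.shape[1])
            # penalty lam ||b||^2 on the summed log-loss  <=>  C = 1/(2 lam)
            clf = LogisticRegression(C=1.0 / (2.0 * self.lam), max_iter=2000)
            clf.fit(S[:, idx], labels)
            self.clf_idx_ = idx
            self.clf_coef_ = clf.coef_[0].copy()
            self.clf_intercept_ = float(clf.intercept_[0])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.x_mean_) / self.x_sd_
        return ((Z - self.pca_mean_) @ self.components_.T) / self.score_sd_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.coef_ + self.intercept_

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        idx = getattr(self, "clf_idx_", np.arange(len(self.clf_coef_)))
        return self.transform(X)[:, idx] @ self.clf_coef_ + self.clf_intercept_


def _split(rng: np.random.Generator, n: int, frac: float,
           stratify: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One random train/test index split; stratified per class when asked."""
    if stratify is None:
        perm = rng.permutation(n)
        n_train = max(1, int(round(frac * n)))
        return perm[:n_train], perm[n_train:]
    train, test = [], []
    for value in np.unique(stratify):
        idx = rng.permutation(np.flatnonzero(stratify == value))
        n_train = min(len(idx) - 1, max(1, int(round(frac * len(idx)))))
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.array(sorted(train)), np.array(sorted(test))


# --------------------------------------------------------------------------
# The serializable fitted model

@dataclass
class PtaModel:
    """Fitted vectorize -> PCA -> ridge predictor of PTA, serializable."""

    feature_labels: tuple[str, ...]
    lam: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    pca_mean: np.ndarray
    components: np.ndarray
    score_sd: np.ndarray
    coef: np.ndarray
    intercept: float
    clf_coef: np.ndarray | None = None
    clf_intercept: float | None = None
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # Canonical contiguous float64 arrays so that predictions are
        # bit-identical before and after a JSON round trip.
        for name in ("x_mean", "x_sd", "pca_mean", "components", "score_sd", "coef"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name), dtype=float))
        if self.clf_coef is not None:
            self.clf_coef = np.ascontiguousarray(self.clf_coef, dtype=float)

    @property
    def n_features(self) -> int:
        return len(self.x_mean)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def component_scores(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature length {X.shape[1]} does not match model ({self.n_features})"
            )
        Z = (X - self.x_mean) / self.x_sd
        return ((Z - self.pca_mean) @ self.components.T) / self.score_sd

    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a).tolist()

        obj = {
            "format": "qvcv-pta-model",
            "version": 1,
            "feature_labels": list(self.feature_labels),
            "lambda": self.lam,
            "x_mean": arr(self.x_mean),
            "x_sd": arr(self.x_sd),
            "pca_mean": arr(self.pca_mean),
            "components": arr(self.components),
            "score_sd": arr(self.score_sd),
            "coef": arr(self.coef),
            "intercept": self.intercept,
            "clf_coef": arr(self.clf_coef) if self.clf_coef is not None else None,
            "clf_intercept": self.clf_intercept,
            "training_summary": self.training_summary,
        }
        return json.dumps(obj, ensure_ascii=False, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PtaModel":
        obj = json.loads(text)
        if obj.get("format") != "qvcv-pta-model":
            raise ValueError("not a model file")
        return cls(
            feature_labels=tuple(obj["feature_labels"]),
            lam=float(obj["lambda"]),
            x_mean=np.array(obj["x_mean"]),
            x_sd=np.array(obj["x_sd"]),
            pca_mean=np.array(obj["pca_mean"]),
            components=np.array(obj["components"]),
            score_sd=np.array(obj["score_sd"]),
            coef=np.array(obj["coef"]),
            intercept=float(obj["intercept"]),
            clf_coef=np.array(obj["clf_coef"]) if obj["clf_coef"] is not None else None,
            clf_intercept=obj["clf_intercept"],
            training_summary=obj.get("training_summary", {}),
        )


def predict_ppta(model: PtaModel, features: np.ndarray) -> np.ndarray | float:
    """Deterministic PPTA for one feature vector or a stack of them.

    Output is clipped to the plausible audiometric range [-10, 80] dB HL.
    """
    scalar = np.asarray(features).ndim == 1
    S = model.component_scores(features)
    out = np.clip(S @ model.coef + model.intercept, *PPTA_CLIP)
    return float(out[0]) if scalar else out


# --------------------------------------------------------------------------
# Fitting with repeated cross-validation

def fit_pta_model(
    features: np.ndarray,
    measured_pta: Sequence[float],
    hl_labels: Sequence[int] | None = None,
    lam: float = DEFAULT_LAMBDA,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    n_repeats: int = DEFAULT_N_REPEATS,
    pca_variance: float = DEFAULT_PCA_VARIANCE,
    seed: int = 0,
    feature_labels: Sequence[str] | None = None,
    min_listeners: int = 20,
) -> tuple[PtaModel, np.ndarray]:
    """Fit the PTA predictor and return cross-validated PPTA per listener.

    For each of ``n_repeats`` seeded random splits, the standardization,
    PCA and ridge regression are fitted on the training fraction only and
    the held-out listeners receive predictions; each listener's PPTA is the
    mean of predictions over the splits in which they were held out.  The
    returned model itself is refitted on all listeners (its deterministic
    predictions are used for new data), with the cross-validated MAE and
    split bookkeeping in ``training_summary``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(measured_pta, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("features and measured_pta disagree in length")
    if n < min_listeners:
        raise ValueError(f"need >= {min_listeners} listeners, got {n}")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    labels = None if hl_labels is None else np.asarray(hl_labels, dtype=int)

    rng = np.random.default_rng(seed)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n, dtype=int)
    train_mae = []
    for _ in range(n_repeats):
        tr, te = _split(rng, n, split_fraction)
        pipe = _Pipeline(lam, pca_variance).fit(X[tr], y[tr])
        pred_sum[te] += np.clip(pipe.predict(X[te]), *PPTA_CLIP)
        pred_cnt[te] += 1
        train_mae.append(np.abs(np.clip(pipe.predict(X[tr]), *PPTA_CLIP) - y[tr]).mean())
    if (pred_cnt == 0).any():
        # A listener never held out (tiny n_repeats): fall back to train-side
        # prediction from a final refit so every listener has a PPTA.
        missing = pred_cnt == 0
    else:
        missing = np.zeros(n, dtype=bool)
    ppta_cv = np.where(~missing, pred_sum / np.maximum(pred_cnt, 1), np.nan)

    final = _Pipeline(lam, pca_variance).fit(X, y)
    if missing.any():
        ppta_cv[missing] = np.clip(final.predict(X[missing]), *PPTA_CLIP)

    clf_coef = clf_intercept = None
    single_class_note = None
    if labels is not None:
        try:
            final.fit(X, y, labels=labels)
            clf_coef = final.clf_coef_
            clf_intercept = final.clf_intercept_
        except ValueError as exc:
            single_class_note = str(exc)

    mae_cv = float(np.abs(ppta_cv - y).mean())
    model = PtaModel(
        feature_labels=tuple(feature_labels) if feature_labels is not None
        else tuple(f"f{i}" for i in range(X.shape[1])),
        lam=lam,
        x_mean=final.x_mean_,
        x_sd=final.x_sd_,
        pca_mean=final.pca_mean_,
        components=final.components_,
        score_sd=final.score_sd_,
        coef=final.coef_,
        intercept=final.intercept_,
        clf_coef=clf_coef,
        clf_intercept=clf_intercept,
        training_summary={
            "n_listeners": n,
            "n_repeats": n_repeats,
            "split_fraction": split_fraction,
            "seed": seed,
            "pca_variance": pca_variance,
            "n_components_final": int(final.components_.shape[0]),
            "mae_cv": mae_cv,
            "mae_train": float(np.mean(train_mae)),
            "classifier_note": single_class_note,
        },
    )
    return model, ppta_cv


# --------------------------------------------------------------------------
# Audibility function and residual loss

@dataclass(frozen=True)
class AudibilityFunction:
    """Piecewise baseline a(p) = max(floor, p); floor ~ 15 dB HL."""

    floor_db_hl: float
    flagged: bool = False

    @property
    def breakpoint_db_hl(self) -> float:
        return self.floor_db_hl

    def __call__(self, pta_db_hl) -> np.ndarray | float:
        p = np.asarray(pta_db_hl, dtype=float)
        out = np.maximum(self.floor_db_hl, p)
        return float(out) if out.ndim == 0 else out


def fit_audibility(
    measured_pta: Sequence[float], ppta: Sequence[float]
) -> AudibilityFunction:
    """Least-squares fit of a(p) = max(floor, p) with floor as the only knob.

    Candidate floors are the means of predicted PTA over every prefix of
    listeners sorted by measured PTA (the stationary points of the
    objective), plus the measured values themselves (its kinks); the
    candidate minimizing the true sum of squares wins.  When no listener
    falls below the fitted floor the floor is unidentified and flagged.
    """
    p = np.asarray(measured_pta, dtype=float)
    q = np.asarray(ppta, dtype=float)
    if p.size != q.size or p.size < 2:
        raise ValueError("need paired measured/predicted PTA, n >= 2")
    order = np.argsort(p, kind="stable")
    ps, qs = p[order], q[order]
    cand = set(np.cumsum(qs)[: p.size] / np.arange(1, p.size + 1))
    cand.update(ps)
    cand.add(ps.min() - 1.0)

    def sse(floor: float) -> float:
        return float(np.sum((q - np.maximum(floor, p)) ** 2))

    floor = min(sorted(cand), key=sse)
    flagged = not bool((p < floor).any())
    return AudibilityFunction(floor_db_hl=float(floor), flagged=flagged)


@dataclass(frozen=True)
class ResidualLossResult:
    """Residual hearing loss: predicted loss beyond the audibility baseline."""

    rhl_db: float
    excess_flag: bool
    threshold_db: float = DEFAULT_EXCESS_THRESHOLD_DB


def residual_loss(
    ppta: float,
    measured_pta: float,
    audibility: AudibilityFunction,
    threshold_db: float = DEFAULT_EXCESS_THRESHOLD_DB,
) -> ResidualLossResult:
    """RHL = PPTA - a(measured PTA); excess iff strictly above threshold."""
    rhl = float(ppta) - float(audibility(measured_pta))
    return ResidualLossResult(
        rhl_db=rhl, excess_flag=rhl > threshold_db, threshold_db=threshold_db
    )


# --------------------------------------------------------------------------
# Cross-validated classification heads (excess loss, NH/HL)

def classification_auc(
    features: np.ndarray,
    labels: Sequence[int],
    lam: float = DEFAULT_LAMBDA,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    n_repeats: int = DEFAULT_N_REPEATS,
    pca_variance: float = DEFAULT_PCA_VARIANCE,
    seed: int = 0,
) -> float:
    """Cross-validated ROC AUC of the regularized logistic head.

    Stratified 70/30 splits are repeated; each listener's score is the mean
    held-out decision value, and the AUC is computed on those scores.  The
    number of component covariates offered to the classifier is capped by
    the events-per-variable >= 10 rule (minimum one), since rare-event
    heads fitted on tens of components learn spurious directions.
    """
    X = np.asarray(features, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if len(np.unique(lab)) != 2:
        raise ValueError("labels must contain exactly two classes")
    if min(np.bincount(lab)) < 3:
        raise ValueError("need >= 3 listeners in each class")
    rng = np.random.default_rng(seed)
    n = len(lab)
    score_sum = np.zeros(n)
    score_cnt = np.zeros(n, dtype=int)
    for _ in range(n_repeats):
        tr, te = _split(rng, n, split_fraction, stratify=lab)
        pipe = _Pipeline(lam, pca_variance).fit(
            X[tr], labels=lab[tr], clf_epv_cap=True
        )
        score_sum[te] += pipe.decision_function(X[te])
        score_cnt[te] += 1
    ok = score_cnt > 0
    return float(roc_auc_score(lab[ok], score_sum[ok] / score_cnt[ok]))


def excess_loss_auc(
    features: np.ndarray,
    xl_labels: Sequence[int],
    lam: float = DEFAULT_LAMBDA,
    seed: int = 0,
    n_repeats: int = DEFAULT_N_REPEATS,
) -> float:
    """AUC for predicting excess-loss status from confusion features alone."""
    return classification_auc(
        features, xl_labels, lam=lam, seed=seed, n_repeats=n_repeats
    )
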