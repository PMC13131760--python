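"""The vectorize -> PCA -> ridge PTA predictor, audibility and residual loss."""

import numpy as np
import pytest

from qvcv import (
    AudibilityFunction,
    ConfusionMatrix,
    OTHER,
    PtaModel,
    classification_auc,
    excess_loss_auc,
    fit_audibility,
    fit_pta_model,
    predict_ppta,
    residual_loss,
    vectorize_ccm,
)


class TestVectorize:
    def test_identity_matrix_gives_indicator_vector(self, panel):
        labels = panel.consonants
        counts = np.zeros((10, 11), dtype=int)
        np.fill_diagonal(counts, 20)
        cm = ConfusionMatrix(labels, labels + (OTHER,), counts)
        v = vectorize_ccm(cm)
        assert v.shape == (110,)
        assert v.sum() == pytest.approx(10.0)
        assert set(np.unique(v)) == {0.0, 1.0}

    def test_rows_normalized(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 30, size=(3, 4))
        cm = ConfusionMatrix(("b", "d", "g"), ("b", "d", "g", OTHER), counts)
        v = vectorize_ccm(cm).reshape(3, 4)
        assert np.allclose(v.sum(axis=1), 1.0)

    def test_empty_row_rejected(self):
        counts = np.array([[3, 0, 1], [0, 0, 0]])
        cm = ConfusionMatrix(("b", "d"), ("b", "d", OTHER), counts)
        with pytest.raises(ValueError, match="zero trials"):
            vectorize_ccm(cm)


def ridge_pca_oracle(X, y, lam, pca_variance, Xnew):
    """Normal-equations oracle: standardize, eigendecompose the covariance,
    retain components, standardize scores, solve (S'S + 2*lam I) b = S'y."""
    mu, sd = X.mean(0), X.std(0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    C = np.cov(Z, rowvar=False, ddof=1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    ratio = np.cumsum(w) / w.sum()
    k = int(np.searchsorted(ratio, pca_variance) + 1)
    zc = Z - Z.mean(0)
    S = zc @ V[:, :k]
    ssd = S.std(0)
    ssd = np.where(ssd > 0, ssd, 1.0)
    S = S / ssd
    beta = np.linalg.solve(S.T @ S + 2 * lam * np.eye(k), S.T @ (y - y.mean()))
    Znew = (Xnew - mu) / sd - Z.mean(0)
    Snew = (Znew @ V[:, :k]) / ssd
    return Snew @ beta + y.mean()


class TestFit:
    def test_matches_normal_equations_oracle_on_tiny_instance(self):
        """Full-data ridge-on-PCA predictions equal an independently coded
        normal-equations solution to 1e-8 (n=8, 4 features)."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        y = rng.uniform(10, 40, size=8)
        model, _ = fit_pta_model(
            X, y, lam=3.0, n_repeats=5, seed=0, min_listeners=8
        )
        got = predict_ppta(model, X)
        want = ridge_pca_oracle(X, y, 3.0, 0.95, X)
        assert np.allclose(got, want, atol=1e-8)

    def test_noise_free_linear_features_recovered_as_lambda_vanishes(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 55, size=30)
        W = rng.normal(size=(1, 6))
        X = y[:, None] @ W + 5.0
        model, ppta = fit_pta_model(X, y, lam=1e-8, n_repeats=60, seed=2)
        assert np.abs(ppta - y).mean() < 0.3

    def test_huge_lambda_collapses_to_training_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 5))
        y = rng.uniform(0, 50, size=25)
        model, _ = fit_pta_model(X, y, lam=1e6, n_repeats=5, seed=0)
        assert predict_ppta(model, X) == pytest.approx(y.mean(), abs=1e-2)

    def test_features_at_training_mean_predict_intercept(self, fitted_model, excess_cohort):
        model, _ = fitted_model
        ppta = predict_ppta(model, excess_cohort["X"].mean(axis=0))
        assert ppta == pytest.approx(excess_cohort["true_pta"].mean(), abs=1e-6)

    def test_near_identity_ccm_predicts_nh_band(self, fitted_model, panel):
        """A listener scoring above 90% maps into the normal-hearing band."""
        counts = np.zeros((10, 11), dtype=int)
        np.fill_diagonal(counts, 19)
        counts[:, -1] = 1  # one OTHER slip per consonant: 95% correct
        cm = ConfusionMatrix(panel.consonants, panel.response_set, counts)
        model, _ = fitted_model
        assert predict_ppta(model, vectorize_ccm(cm)) <= 20.0

    def test_feature_length_mismatch_rejected(self, fitted_model):
        model, _ = fitted_model
        with pytest.raises(ValueError, match="feature length"):
            predict_ppta(model, np.zeros(7))

    def test_cv_mae_not_below_training_mae(self, panel):
        """Held-out error exceeds training error on average (no leakage)."""
        from qvcv import cohort_feature_matrix, simulate_cohort

        diffs = []
        for s in range(3):
            trials, _, profs = simulate_cohort(
                6, panel=panel, trials_per_token=5, n_sessions=1, seed=60 + s
            )
            ids, X = cohort_feature_matrix(trials, panel)
            prof = {p.listener_id: p for p in profs}
            y = np.array([prof[i].true_pta_db_hl for i in ids])
            model, _ = fit_pta_model(X, y, lam=3.0, n_repeats=40, seed=s)
            diffs.append(
                model.training_summary["mae_cv"] - model.training_summary["mae_train"]
            )
        assert np.mean(diffs) > 0

    def test_identical_seed_identical_predictions(self, excess_cohort):
        a = fit_pta_model(excess_cohort["X"], excess_cohort["true_pta"],
                          lam=3.0, n_repeats=20, seed=9)[1]
        b = fit_pta_model(excess_cohort["X"], excess_cohort["true_pta"],
                          lam=3.0, n_repeats=20, seed=9)[1]
        assert (a == b).all()

    def test_serialization_round_trip_bit_identical(self, fitted_model, excess_cohort):
        model, _ = fitted_model
        again = PtaModel.from_json(model.to_json())
        p1 = predict_ppta(model, excess_cohort["X"])
        p2 = predict_ppta(again, excess_cohort["X"])
        assert (p1 == p2).all()

    def test_too_few_listeners_rejected(self):
        with pytest.raises(ValueError, match="listeners"):
            fit_pta_model(np.zeros((5, 3)), np.zeros(5))


class TestAudibility:
    def test_pointwise_values(self):
        a = AudibilityFunction(floor_db_hl=15.0)
        assert a(10) == 15.0
        assert a(40) == 40.0
        assert a(15) == 15.0
        assert a.breakpoint_db_hl == 15.0

    def test_noise_free_floor_recovered_exactly(self):
        pta = np.array([-5.0, 0.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 12.0, 3.0])
        ppta = np.maximum(15.0, pta)
        fit = fit_audibility(pta, ppta)
        assert fit.floor_db_hl == pytest.approx(15.0, abs=1e-9)
        assert not fit.flagged

    def test_all_hl_cohort_flagged(self):
        pta = np.array([20.0, 30.0, 40.0, 50.0])
        fit = fit_audibility(pta, pta)
        assert fit.flagged
        assert fit.floor_db_hl <= pta.min()

    def test_floor_recovered_under_noise(self):
        """Floor within +/-1 dB on 200-listener cohorts with 3 dB noise,
        50 seeded replicates."""
        errs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            pta = rng.uniform(-10, 55, size=200)
            ppta = np.maximum(15.0, pta) + rng.normal(0, 3, size=200)
            errs.append(abs(fit_audibility(pta, ppta).floor_db_hl - 15.0))
        assert np.mean(np.array(errs) <= 1.0) >= 0.9


class TestResidualLoss:
    def test_excess_case(self):
        r = residual_loss(30.0, 10.0, AudibilityFunction(15.0))
        assert r.rhl_db == 15.0 and r.excess_flag

    def test_zero_residual_not_excess(self):
        a = AudibilityFunction(15.0)
        r = residual_loss(float(a(40.0)), 40.0, a)
        assert r.rhl_db == 0.0 and not r.excess_flag

    def test_negative_residual(self):
        r = residual_loss(20.0, 40.0, AudibilityFunction(15.0))
        assert r.rhl_db == -20.0 and not r.excess_flag

    def test_threshold_is_strict(self):
        r = residual_loss(20.0, 15.0, AudibilityFunction(15.0))
        assert r.rhl_db == 5.0 and not r.excess_flag


class TestClassification:
    def test_labels_independent_of_features_near_chance(self):
        """Random labels give cross-validated AUC near 0.5 on average."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 12))
        aucs = []
        for s in range(10):
            lab = np.zeros(60, dtype=int)
            lab[rng.permutation(60)[:10]] = 1
            aucs.append(classification_auc(X, lab, seed=s))
        assert abs(np.mean(aucs) - 0.5) < 0.13

    def test_label_determined_by_latent_feature_separates(self):
        """Labels driven by a latent factor loading on several feature
        cells (the structure a loss manifold produces) are recovered with
        AUC near 1."""
        rng = np.random.default_rng(1)
        u = rng.normal(size=60)
        X = rng.normal(size=(60, 12)) * 0.5
        X[:, :5] += np.outer(u, rng.uniform(0.8, 1.2, 5))
        labels = (u > np.percentile(u, 60)).astype(int)
        assert classification_auc(X, labels, seed=0) > 0.95

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            excess_loss_auc(np.zeros((10, 3)), np.ones(10, dtype=int))
        with pytest.raises(ValueError, match=">= 3"):
            excess_loss_auc(np.zeros((10, 3)), np.r_[np.ones(2), np.zeros(8)].astype(int))
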