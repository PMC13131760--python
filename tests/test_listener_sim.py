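"""Synthetic-listener generator: response model, calibration, cohorts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from qvcv import (
    ListenerProfile,
    build_confusion_matrix,
    calibrate_token_models,
    cohort_feature_matrix,
    fit_audibility,
    fit_pta_model,
    make_confusion_kernel,
    score_percent_correct,
    simulate_cohort,
    simulate_trial,
)
from qvcv.listener_sim import (
    LOSS_KNEE_DB_HL,
    TokenModel,
    feature_distance,
    make_deep_confusion_kernel,
)


@pytest.fixture(scope="module")
def token_models(panel):
    return calibrate_token_models(panel, rng=np.random.default_rng(0))


class TestResponseModel:
    def test_trial_probability_matches_closed_form(self, panel, token_models):
        """Empirical P(correct) over 1e5 seeded trials sits within 3 sigma
        of the closed-form response model."""
        tm = token_models[("d", "ɑ")]
        profile = ListenerProfile("L1", true_pta_db_hl=35.0)
        snr = float(panel["d"].snr_db)
        p_expected = tm.p_correct(snr, profile.effective_loss())
        rng = np.random.default_rng(123)
        n = 100_000
        hits = sum(
            simulate_trial(profile, tm, snr, rng).correct for _ in range(n)
        )
        se = np.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(hits / n - p_expected) < 3 * se

    def test_loss_below_knee_has_no_effect(self, token_models):
        tm = token_models[("s", "ɑ")]
        assert tm.p_correct(0.0, -10.0) == tm.p_correct(0.0, 15.0)
        assert tm.p_correct(0.0, 16.0) < tm.p_correct(0.0, 15.0)

    def test_steep_slope_far_above_midpoint_always_correct(self):
        tm = TokenModel(
            token=("b", "ɑ"), midpoint_db=0.0, slope_per_db=1e6,
            loss_shift_per_db=0.0,
            confusion_kernel=make_confusion_kernel("b", ("b", "d", "OTHER")),
        )
        profile = ListenerProfile("L1", 0.0, lapse=0.0)
        rng = np.random.default_rng(0)
        trials = [simulate_trial(profile, tm, 40.0, rng) for _ in range(200)]
        assert all(t.correct for t in trials)

    def test_effective_loss_composition(self):
        p = ListenerProfile("L1", 30.0, excess_offset_db=10.0, aided_relief_db=15.0)
        assert p.effective_loss() == 40.0
        assert p.effective_loss(aided=True) == 25.0
        floor = ListenerProfile("L2", -10.0, aided_relief_db=20.0)
        assert floor.effective_loss(aided=True) == -10.0


class TestCalibration:
    def test_target_hit_exactly_at_panel_snr(self, panel, token_models):
        """Construction guarantees P(correct) = 0.90 at each token's panel
        SNR for effective loss at the knee."""
        for entry in panel.entries:
            tm = token_models[(entry.consonant, entry.vowel)]
            assert tm.p_correct(entry.snr_db, LOSS_KNEE_DB_HL) == pytest.approx(0.90)

    def test_unreachable_target_rejected(self, panel):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_token_models(panel, target_nh_score=0.99)

    def test_kernel_temperature_limit_is_uniform(self):
        kernel = make_confusion_kernel("s", ("b", "d", "s", "ʃ", "OTHER"),
                                       temperature=1e9)
        probs = np.array(list(kernel.values()))
        assert np.allclose(probs, 1 / len(probs))

    def test_similar_consonants_confused_more(self):
        """/s/ -> /ʃ/ mass exceeds /s/ -> /m/ mass at finite temperature,
        as the feature-distance oracle demands."""
        from qvcv import CONSONANTS, OTHER

        assert feature_distance("s", "ʃ") < feature_distance("s", "m")
        kernel = make_confusion_kernel("s", CONSONANTS + (OTHER,))
        assert kernel["ʃ"] > kernel["m"]

    def test_deep_kernel_spreads_place_errors(self):
        near = make_confusion_kernel("s", ("s", "ʃ", "f", "m", "OTHER"))
        deep = make_deep_confusion_kernel("s", ("s", "ʃ", "f", "m", "OTHER"))
        # with place information gone, /f/ (same manner+voicing) catches up
        # with /ʃ/ and the OTHER button gains mass
        assert deep["f"] == pytest.approx(deep["ʃ"])
        assert deep["OTHER"] > near["OTHER"]


class TestCohorts:
    def test_nh_cohort_scores_near_target(self, panel):
        """Normal-hearing cohorts average close to the 90% normalization
        target at panel SNRs."""
        means = []
        for s in range(5):
            trials, _, _ = simulate_cohort(
                {"NH": 10}, panel=panel, trials_per_token=5, n_sessions=1,
                seed=700 + s,
            )
            ids = sorted({t.listener_id for t in trials})
            means.append(np.mean([
                score_percent_correct(build_confusion_matrix(
                    [t for t in trials if t.listener_id == lid],
                    presented_labels=panel.consonants))
                for lid in ids
            ]))
        assert 88.0 <= np.mean(means) <= 92.0

    def test_moderate_cohort_scores_below_nh(self, panel):
        diffs = []
        for s in range(5):
            nh, _, _ = simulate_cohort({"NH": 5}, panel=panel,
                                       trials_per_token=5, n_sessions=1, seed=800 + s)
            mod, _, _ = simulate_cohort({"moderate": 5}, panel=panel,
                                        trials_per_token=5, n_sessions=1, seed=900 + s)
            score = lambda trials: np.mean([
                score_percent_correct(build_confusion_matrix(
                    [t for t in trials if t.listener_id == lid]))
                for lid in sorted({t.listener_id for t in trials})
            ])
            diffs.append(score(nh) - score(mod))
        assert min(diffs) > 0

    def test_score_non_increasing_in_pta(self, panel, token_models):
        """Expected percent correct declines monotonically with true PTA."""
        ptas = np.arange(-10, 56, 5, dtype=float)
        expected = []
        for pta in ptas:
            p = np.mean([
                token_models[(e.consonant, e.vowel)].p_correct(e.snr_db, pta)
                for e in panel.entries
            ])
            expected.append(p)
        assert (np.diff(expected) <= 1e-12).all()

    def test_no_excess_fraction_means_no_offsets(self, panel):
        _, _, profiles = simulate_cohort(
            {"NH": 2, "slight": 2}, panel=panel, trials_per_token=2,
            excess_fraction=0.0, seed=0,
        )
        assert all(p.excess_offset_db == 0.0 for p in profiles)

    def test_excess_offsets_assigned_to_loss_categories(self, excess_cohort):
        ex = excess_cohort["excess"]
        assert (ex > 0).sum() == 7
        assert (excess_cohort["true_pta"][ex > 0] > 15).all()

    def test_cohort_reproducible_under_seed(self, panel):
        a = simulate_cohort({"mild": 2}, panel=panel, trials_per_token=2, seed=5)
        b = simulate_cohort({"mild": 2}, panel=panel, trials_per_token=2, seed=5)
        assert a[0] == b[0]


class TestModelConsistency:
    def test_ppta_rank_correlates_with_true_pta(self, panel):
        """Fitting the PTA model on calibrated cohorts recovers the true
        PTA ordering (rank correlation >= 0.8)."""
        rhos = []
        for s in range(6):
            trials, _, profiles = simulate_cohort(
                15, panel=panel, trials_per_token=5, n_sessions=2, seed=400 + s
            )
            ids, X = cohort_feature_matrix(trials, panel)
            prof = {p.listener_id: p for p in profiles}
            y = np.array([prof[i].true_pta_db_hl for i in ids])
            _, ppta = fit_pta_model(X, y, lam=3.0, n_repeats=50, seed=500 + s)
            rhos.append(spearmanr(ppta, y).statistic)
        assert min(rhos) >= 0.8

    def test_excess_listeners_show_positive_residuals(
        self, excess_cohort, fitted_model
    ):
        _, ppta = fitted_model
        aud = fit_audibility(excess_cohort["true_pta"], ppta)
        rhl = ppta - aud(excess_cohort["true_pta"])
        ex = excess_cohort["excess"] > 0
        assert rhl[ex].mean() > 0
        assert rhl[ex].mean() > rhl[~ex].mean() + 3.0

    def test_ordinary_listeners_residuals_center_near_zero(self, panel):
        """On cohorts without an excess subgroup the mean residual loss sits
        within +/-2 dB of zero (no gross miscalibration)."""
        means = []
        for s in range(3):
            trials, _, profiles = simulate_cohort(
                15, panel=panel, trials_per_token=5, n_sessions=2, seed=100 + s
            )
            ids, X = cohort_feature_matrix(trials, panel)
            prof = {p.listener_id: p for p in profiles}
            y = np.array([prof[i].true_pta_db_hl for i in ids])
            _, ppta = fit_pta_model(X, y, lam=3.0, n_repeats=100, seed=200 + s)
            aud = fit_audibility(y, ppta)
            means.append((ppta - aud(y)).mean())
        assert abs(np.mean(means)) <= 2.0
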