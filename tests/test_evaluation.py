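import numpy as np
import pytest

from mirratio.core_io import ValidationError
from mirratio.evaluation import (auc, calibration_intercept,
                                 calibration_slope, cochran_armitage,
                                 delong_paired_test, kfold_cv, or_from_2x2,
                                 scaled_brier, univariate_or, youden_cutoff)
from mirratio.selection import LassoConfig, mann_whitney


def sigmoid(x):
    return 1 / (1 + np.exp(-x))


class TestCalibration:
    def test_intercept_near_zero_under_correct_model(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, size=5000)
        y = rng.binomial(1, p)
        assert abs(calibration_intercept(p, y)) < 0.1

    def test_intercept_recovers_uniform_odds_shift(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, size=20000)
        logit = np.log(p / (1 - p))
        y = rng.binomial(1, sigmoid(logit + np.log(2)))
        assert calibration_intercept(p, y) == pytest.approx(np.log(2),
                                                            abs=0.07)

    def test_intercept_zero_for_constant_prevalence_prediction(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        p = np.full(6, y.mean())
        assert calibration_intercept(p, y) == pytest.approx(0, abs=1e-8)

    def test_slope_near_one_under_correct_model(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, size=5000)
        y = rng.binomial(1, p)
        assert calibration_slope(p, y) == pytest.approx(1.0, abs=0.1)

    def test_slope_half_when_logits_doubled(self):
        rng = np.random.default_rng(3)
        logit_true = rng.normal(0, 1.2, size=20000)
        y = rng.binomial(1, sigmoid(logit_true))
        p_over = sigmoid(2 * logit_true)  # overconfident predictions
        assert calibration_slope(p_over, y) == pytest.approx(0.5, abs=0.05)

    def test_refit_probabilities_are_self_consistent(self):
        # predictions from an in-sample ML logistic refit recalibrate to
        # exactly slope 1, intercept 0 on the same data
        import statsmodels.api as sm
        rng = np.random.default_rng(18)
        X = rng.normal(size=(400, 2))
        y = rng.binomial(1, sigmoid(X @ np.array([0.8, -0.5])))
        fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        p_hat = fit.predict(sm.add_constant(X))
        assert calibration_slope(p_hat, y) == pytest.approx(1.0, abs=1e-6)
        assert calibration_intercept(p_hat, y) == pytest.approx(0.0,
                                                                abs=1e-6)

    def test_constant_predictions_have_no_slope(self):
        with pytest.raises(ValidationError):
            calibration_slope(np.full(10, 0.4), np.r_[np.ones(5), np.zeros(5)])


class TestScaledBrier:
    def test_perfect_predictions_score_zero(self):
        y = np.array([1, 0, 1, 0])
        assert scaled_brier(y.astype(float), y) == 0.0

    def test_prevalence_predictor_scores_one(self):
        y = np.array([1, 1, 0, 0, 0])
        assert scaled_brier(np.full(5, y.mean()), y) == pytest.approx(1.0)

    def test_worked_arithmetic(self):
        p = np.array([0.8, 0.6, 0.3, 0.1])
        y = np.array([1, 1, 0, 0])
        # Brier 0.075, null Brier 0.25 at prevalence 0.5
        assert scaled_brier(p, y) == pytest.approx(0.30)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            scaled_brier(np.array([0.5, 0.5]), np.array([1, 1]))


class TestAuc:
    def test_perfect_separation(self):
        a, (lo, hi) = auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert a == 1.0 and hi == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=4000)
        y = rng.binomial(1, 0.5, size=4000)
        assert auc(scores, y, ci=False) == pytest.approx(0.5, abs=0.03)

    def test_equals_mann_whitney_u_over_n1n0(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        y = np.array([1] * 25 + [0] * 35)
        res = mann_whitney(scores[y == 1], scores[y == 0])
        assert auc(scores, y, ci=False) == pytest.approx(
            res.statistic / (25 * 35))

    def test_complement_symmetry(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        y = rng.binomial(1, 0.4, size=50)
        assert auc(scores, y, ci=False) + auc(-scores, y, ci=False) == \
            pytest.approx(1.0)


class TestDeLong:
    def test_identical_scores_give_z_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=40)
        y = rng.binomial(1, 0.5, size=40)
        res = delong_paired_test(p, p, y)
        assert res.z == 0.0 and res.pvalue == 1.0

    def test_informative_beats_noise(self):
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            rng = np.random.default_rng(300 + seed)
            x = rng.normal(size=500)
            y = rng.binomial(1, sigmoid(1.5 * x))
            noise = rng.normal(size=500)
            res = delong_paired_test(sigmoid(1.5 * x), sigmoid(noise), y)
            if res.pvalue < 0.01:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_z_close_to_bootstrap_oracle(self):
        rng = np.random.default_rng(8)
        n = 300
        latent = rng.normal(size=n)
        y = rng.binomial(1, sigmoid(latent))
        p1 = sigmoid(latent + rng.normal(0, 1.0, n))
        p2 = sigmoid(0.3 * latent + rng.normal(0, 1.0, n))
        res = delong_paired_test(p1, p2, y)
        boot = []
        for _ in range(4000):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            boot.append(auc(p1[idx], yb, ci=False)
                        - auc(p2[idx], yb, ci=False))
        z_boot = (res.auc1 - res.auc2) / np.std(boot, ddof=1)
        assert res.z == pytest.approx(z_boot, rel=0.15)


class TestYouden:
    def test_perfect_separation(self):
        res = youden_cutoff([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.youden_j == 1.0
        assert res.sensitivity == res.specificity == 1.0

    def test_cutoff_lies_between_classes(self):
        res = youden_cutoff([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0])
        assert 0.4 < res.cutoff <= 0.8
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_null_scores_give_small_j(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(size=5000)
        y = rng.binomial(1, 0.5, size=5000)
        assert youden_cutoff(scores, y).youden_j < 0.1

    def test_j_identity(self):
        rng = np.random.default_rng(10)
        scores = rng.uniform(size=30)
        y = rng.binomial(1, 0.5, size=30)
        res = youden_cutoff(scores, y)
        assert res.youden_j == pytest.approx(
            res.sensitivity + res.specificity - 1)


class TestOddsRatios:
    def test_cross_product_to_machine_precision(self):
        res = or_from_2x2(14, 49, 9, 57)
        assert res.oddsratio == (14 * 57) / (49 * 9)
        assert res.ci_low < res.oddsratio < res.ci_high

    def test_symmetric_table_is_null(self):
        assert or_from_2x2(10, 10, 10, 10).oddsratio == 1.0

    def test_swapping_exposure_inverts_or(self):
        a = or_from_2x2(12, 30, 8, 40)
        b = or_from_2x2(30, 12, 40, 8)
        assert a.oddsratio == pytest.approx(1 / b.oddsratio)

    def test_zero_cell_reported_not_corrected(self):
        res = or_from_2x2(0, 10, 5, 20)
        assert "zero cell" in res.note

    def test_categorical_dispatch_matches_manual_table(self):
        exposure = np.array(["ref"] * 60 + ["hi"] * 40)
        y = np.r_[np.repeat(1, 20), np.repeat(0, 40),
                  np.repeat(1, 25), np.repeat(0, 15)]
        out = univariate_or(exposure, y, reference="ref")
        assert out["hi"].oddsratio == pytest.approx((25 * 40) / (20 * 15))

    def test_continuous_exposure_per_unit_or(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=3000)
        y = rng.binomial(1, sigmoid(0.7 * x))
        res = univariate_or(x, y)
        assert res.oddsratio == pytest.approx(np.exp(0.7), rel=0.1)
        assert res.ci_low < res.oddsratio < res.ci_high


class TestCochranArmitage:
    def test_matches_hand_formula_on_toy_table(self):
        # levels 0,1,2 with cases/controls 10/30, 20/20, 30/10
        x = np.repeat([0, 1, 2], 40)
        y = np.r_[np.repeat(1, 10), np.repeat(0, 30),
                  np.repeat(1, 20), np.repeat(0, 20),
                  np.repeat(1, 30), np.repeat(0, 10)]
        # hand computation of the trend z-score
        from scipy.stats import norm
        scores = np.array([0., 1., 2.])
        n_i = np.array([40., 40., 40.])
        r_i = np.array([10., 20., 30.])
        pbar = 0.5
        num = np.sum(scores * (r_i - n_i * pbar))
        var = pbar * (1 - pbar) * (np.sum(scores ** 2 * n_i)
                                   - np.sum(scores * n_i) ** 2 / 120)
        expected = 2 * norm.sf(abs(num / np.sqrt(var)))
        assert cochran_armitage(x, y) == pytest.approx(expected, abs=1e-12)

    def test_monotone_trend_detected(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 3, size=300)
        y = rng.binomial(1, 0.2 + 0.25 * x)
        assert cochran_armitage(x, y) < 1e-3

    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(13)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.integers(0, 3, size=120)
            y = rng.binomial(1, 0.4, size=120)
            if cochran_armitage(x, y) < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            cochran_armitage(np.ones(10), np.r_[np.ones(5), np.zeros(5)])


class TestCombinedModel:
    def _cohort(self, seed, n, bmi_effect=0.0, wcrf_effect=0.0):
        from mirratio.synthetic_data import (GeneratorConfig,
                                             generate_cohort_covariates)
        cfg = GeneratorConfig(seed=seed, n_cases=n // 2, n_controls=n // 2,
                              n_mirs=4, n_differential_pairs=1,
                              bmi_class_log_or=bmi_effect,
                              menopause_log_or=0.0, interaction_log_or=0.0,
                              wcrf_log_or=wcrf_effect,
                              tabar_trend_log_or=0.0)
        cov, _, _ = generate_cohort_covariates(cfg)
        return cov, cov["label"].to_numpy()

    def test_heavy_penalty_reduces_to_intercept_only(self):
        from mirratio.evaluation import fit_combined_model
        rng = np.random.default_rng(17)
        cov, y = self._cohort(17, 200)
        ratios = rng.normal(size=(200, 3))
        model = fit_combined_model(ratios, ["r1", "r2", "r3"], cov, y,
                                   LassoConfig(lambda_=100.0))
        assert model.selected == []

    def test_true_covariate_effects_are_selected(self):
        from mirratio.evaluation import fit_combined_model
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            rng = np.random.default_rng(600 + seed)
            cov, y = self._cohort(600 + seed, 1000, bmi_effect=0.9,
                                  wcrf_effect=-0.5)
            ratios = rng.normal(size=(1000, 2))  # pure noise features
            model = fit_combined_model(ratios, ["r1", "r2"], cov, y,
                                       LassoConfig(seed=seed))
            if {"bmi_class", "wcrf"} <= set(model.selected):
                hits += 1
        assert hits >= int(0.9 * n_seeds)


class TestKfoldCv:
    def test_same_seed_reproduces_everything(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(120, 4))
        y = rng.binomial(1, sigmoid(X[:, 0]))
        cfg = LassoConfig(lambda_=0.02, seed=3)
        a = kfold_cv(X, y, cfg, seed=5)
        b = kfold_cv(X, y, cfg, seed=5)
        assert a == b

    def test_well_specified_model_is_calibrated(self):
        rng = np.random.default_rng(15)
        n = 2000
        X = rng.normal(size=(n, 3))
        y = rng.binomial(1, sigmoid(X @ np.array([1.0, -0.6, 0.3])))
        perf = kfold_cv(X, y, LassoConfig(lambda_=0.001), k=5, seed=0)
        assert 0.9 <= perf.calibration_slope <= 1.1
        assert abs(perf.calibration_intercept) < 0.15
        assert perf.auc > 0.7

    def test_shuffled_labels_have_no_signal(self):
        rng = np.random.default_rng(16)
        aucs = []
        for seed in range(8):
            X = rng.normal(size=(150, 5))
            y = rng.binomial(1, 0.5, size=150)
            perf = kfold_cv(X, y, LassoConfig(lambda_=0.05, seed=seed),
                            k=5, seed=seed)
            aucs.append(perf.auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.07)
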