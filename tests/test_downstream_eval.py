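import numpy as np
import pandas as pd
import pytest

from mrbiom.core_io import ExpressionMatrix, SampleTable
from mrbiom.downstream_eval import (
    CVReport,
    RiskModel,
    cox_multivariate_fit,
    cox_univariate_screen,
    downsample_balance,
    filter_cohort,
    kfold_cv,
    km_logrank,
    make_classifier,
    median_split,
    risk_scores,
    survival_roc,
)
from mrbiom.synthetic_data import simulate_survival


def _samples(n_case, n_control):
    ids = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_control)]
    return SampleTable(
        pd.DataFrame(
            {"sample_id": ids, "condition": ["case"] * n_case + ["control"] * n_control}
        )
    )


def _surv_table(ids, days, events, condition="case"):
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "condition": condition,
                "os_days": days,
                "os_event": events,
            }
        )
    )


class TestDownsample:
    def test_full_request_keeps_all_cases(self):
        samples = _samples(5, 3)
        out = downsample_balance(samples, 5, 3, seed=0)
        assert sorted(out.sample_ids) == sorted(samples.sample_ids)

    def test_deterministic_under_seed(self):
        samples = _samples(30, 10)
        a = downsample_balance(samples, 10, 5, seed=7)
        b = downsample_balance(samples, 10, 5, seed=7)
        assert a.sample_ids == b.sample_ids

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="available"):
            downsample_balance(_samples(3, 3), 5, 2, seed=0)

    def test_sampling_frequencies_uniform(self):
        samples = _samples(20, 2)
        counts = {f"c{i}": 0 for i in range(20)}
        n_rep, n_pick = 1000, 5
        for seed in range(n_rep):
            out = downsample_balance(samples, n_pick, 2, seed=seed)
            for s in out.ids_of("case"):
                counts[s] += 1
        p = n_pick / 20
        se = np.sqrt(p * (1 - p) / n_rep)
        for c in counts.values():
            assert abs(c / n_rep - p) < 3.5 * se


class TestCVReport:
    def test_averages_are_fold_means(self):
        r = CVReport([0.9, 1.0], [0.8, 1.0], [1.0, 1.0])
        assert r.mean_accuracy == pytest.approx(0.95)
        assert r.mean_sensitivity == pytest.approx(0.9)
        assert r.mean_specificity == pytest.approx(1.0)

    def test_mismatched_folds_rejected(self):
        with pytest.raises(ValueError):
            CVReport([0.9], [0.8, 0.7], [1.0])


class TestKfoldCV:
    @staticmethod
    def _cohort(rng, n=40, sep=3.0):
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        x = rng.normal(size=(5, n)) + sep * y[None, :]
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"s{j}" for j in range(n)], np.abs(x) + 0.1
        )
        return expr, y

    def test_folds_partition_and_stratify(self, rng):
        seen = []

        def spy(x_train, y_train, x_test):
            seen.append((len(y_train), x_test.shape[0]))
            return np.ones(x_test.shape[0], dtype=int)

        expr, y = self._cohort(rng)
        report = kfold_cv(expr, y, k=5, fit_predict=spy, seed=1)
        assert len(report.accuracy) == 5
        assert sum(n_test for _, n_test in seen) == 40

    def test_always_positive_predictor_has_zero_specificity(self, rng):
        expr, y = self._cohort(rng)
        report = kfold_cv(
            expr, y, k=4, fit_predict=lambda a, b, c: np.ones(c.shape[0], int), seed=0
        )
        assert report.mean_sensitivity == 1.0
        assert report.mean_specificity == 0.0

    @pytest.mark.parametrize("kind", ["rf", "svm", "nb"])
    def test_plugin_classifiers_separate_planted_classes(self, rng, kind):
        expr, y = self._cohort(rng, n=40, sep=4.0)
        report = kfold_cv(expr, y, k=5, fit_predict=make_classifier(kind, 0), seed=0)
        assert report.mean_accuracy > 0.9


class TestFilterCohort:
    def test_boundaries_and_missing(self):
        t = _surv_table(
            ["a", "b", "c"], [29.0, 30.0, np.nan], [1.0, 0.0, np.nan]
        )
        kept = filter_cohort(t, min_days=30)
        assert kept.sample_ids == ["b"]


class TestCoxScreen:
    @staticmethod
    def _simulated(rng, beta, n=300, censoring=0.2):
        x = rng.normal(size=n)
        expr = ExpressionMatrix(["g"], [f"p{i}" for i in range(n)], np.abs(x[None, :]) + 0.01)
        # direct exponential simulation on the covariate x
        rate = 0.01 * np.exp(beta * x)
        times = rng.exponential(1 / rate)
        cens = rng.exponential(1 / (0.01 * censoring * 4 + 1e-9), size=n) if censoring else np.full(n, np.inf)
        days = np.minimum(times, cens)
        events = (times <= cens).astype(int)
        expr = ExpressionMatrix(["g"], expr.sample_ids, (x - x.min() + 0.01)[None, :])
        samples = _surv_table(expr.sample_ids, days, events)
        return expr, samples

    def test_null_covariate_retained_near_alpha_rate(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            expr, samples = self._simulated(rng, beta=0.0, n=120, censoring=0)
            hits += bool(cox_univariate_screen(expr, samples, alpha=0.05))
        # binomial(100, 0.05): 3 sigma band around 5
        assert hits <= 13

    def test_strong_covariate_retained(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(20):
            expr, samples = self._simulated(rng, beta=1.0, n=300, censoring=0)
            hits += bool(cox_univariate_screen(expr, samples, alpha=0.05))
        assert hits >= 19

    def test_constant_covariate_skipped_with_warning(self):
        expr = ExpressionMatrix(["g"], ["a", "b", "c", "d"], [[2.0, 2.0, 2.0, 2.0]])
        samples = _surv_table(["a", "b", "c", "d"], [10, 20, 30, 40], [1, 1, 0, 1])
        with pytest.warns(UserWarning, match="constant"):
            assert cox_univariate_screen(expr, samples) == []


class TestCoxMultivariate:
    def test_single_covariate_reduces_to_univariate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        rate = 0.01 * np.exp(0.8 * x)
        times = rng.exponential(1 / rate)
        expr = ExpressionMatrix(["g"], [f"p{i}" for i in range(200)], (x - x.min() + 0.01)[None, :])
        samples = _surv_table(expr.sample_ids, times, np.ones(200, int))
        model = cox_multivariate_fit(expr, samples, alpha=0.05)
        from lifelines import CoxPHFitter

        frame = pd.DataFrame({"g": expr.values[0], "os_days": times, "os_event": 1})
        ref = CoxPHFitter().fit(frame, "os_days", "os_event")
        assert model.coefficients[0] == pytest.approx(ref.params_["g"], abs=1e-8)

    def test_cutoff_is_median_training_score(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 151))
        rate = 0.01 * np.exp(0.9 * x[0] - 0.7 * x[1])
        times = rng.exponential(1 / rate)
        expr = ExpressionMatrix(["g1", "g2"], [f"p{i}" for i in range(151)], np.abs(x) + 0.01)
        expr = ExpressionMatrix(["g1", "g2"], expr.sample_ids, x - x.min() + 0.01)
        samples = _surv_table(expr.sample_ids, times, np.ones(151, int))
        model = cox_multivariate_fit(expr, samples, alpha=0.9)
        scores = risk_scores(expr, model)
        assert model.cutoff == pytest.approx(float(np.median(scores)))


class TestRiskScores:
    def test_zero_expression_scores_zero(self):
        model = RiskModel(["a", "b"], np.array([0.5, -1.0]), cutoff=0.0)
        expr = ExpressionMatrix(["a", "b"], ["s1"], [[0.0], [0.0]])
        assert risk_scores(expr, model)["s1"] == 0.0

    def test_published_style_coefficient_sum_at_unit_expression(self):
        model = RiskModel(
            ["LMNB2", "BGN", "MFSD12", "SOX4"],
            np.array([-0.5295, 0.2133, -0.6516, 0.2814]),
            cutoff=0.0,
        )
        expr = ExpressionMatrix(model.pmb_ids, ["s1"], np.ones((4, 1)))
        assert risk_scores(expr, model)["s1"] == pytest.approx(-0.6864, abs=1e-12)

    def test_linearity(self, rng):
        model = RiskModel(["a", "b", "c"], rng.normal(size=3), cutoff=0.0)
        vals = rng.uniform(0, 10, size=(3, 5))
        expr = ExpressionMatrix(["a", "b", "c"], [f"s{i}" for i in range(5)], vals)
        scaled = ExpressionMatrix(["a", "b", "c"], expr.sample_ids, 3.0 * vals)
        np.testing.assert_allclose(
            risk_scores(scaled, model).to_numpy(),
            3.0 * risk_scores(expr, model).to_numpy(),
            atol=1e-10,
        )


class TestMedianSplit:
    def test_strict_rule_small_example(self):
        groups = median_split(pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]))
        assert groups["c"] == "high" and groups["a"] == "low" and groups["b"] == "low"

    def test_odd_cohort_splits_134_135(self, rng):
        scores = pd.Series(rng.permutation(np.linspace(-5, 5, 269)))
        groups = median_split(scores)
        assert (groups == "high").sum() == 134
        assert (groups == "low").sum() == 135
        median_holder = scores.idxmax() if False else scores[scores == np.median(scores)].index[0]
        assert groups[median_holder] == "low"

    def test_all_equal_scores_warn(self):
        with pytest.warns(UserWarning, match="equal"):
            groups = median_split(pd.Series([2.0, 2.0, 2.0]))
        assert (groups == "low").all()


class TestKmLogrank:
    def test_km_starts_at_one_and_null_p_large(self):
        rng = np.random.default_rng(8)
        n = 300
        times = rng.exponential(500, size=n)
        ids = [f"p{i}" for i in range(n)]
        samples = _surv_table(ids, times, np.ones(n, int))
        groups = pd.Series(np.where(np.arange(n) % 2 == 0, "high", "low"), index=ids)
        curves, p = km_logrank(groups, samples)
        for curve in curves.values():
            assert curve.iloc[0, 0] == pytest.approx(1.0)
        assert p > 0.05

    def test_strong_hazard_difference_detected(self):
        rng = np.random.default_rng(9)
        n = 200
        half = n // 2
        times = np.concatenate(
            [rng.exponential(100, half), rng.exponential(400, half)]
        )
        ids = [f"p{i}" for i in range(n)]
        samples = _surv_table(ids, times, np.ones(n, int))
        groups = pd.Series(["high"] * half + ["low"] * half, index=ids)
        _, p = km_logrank(groups, samples)
        assert p < 0.001

    def test_single_group_rejected(self):
        samples = _surv_table(["a", "b"], [10, 20], [1, 1])
        groups = pd.Series(["high", "high"], index=["a", "b"])
        with pytest.raises(ValueError, match="two"):
            km_logrank(groups, samples)


class TestSurvivalRoc:
    def test_constant_scores_give_half(self):
        rng = np.random.default_rng(10)
        n = 100
        times = rng.exponential(300, n)
        ids = [f"p{i}" for i in range(n)]
        samples = _surv_table(ids, times, np.ones(n, int))
        scores = pd.Series(np.ones(n), index=ids)
        assert survival_roc(scores, samples, horizon=float(np.median(times))) == pytest.approx(
            0.5
        )

    def test_true_log_hazard_scores_discriminate(self):
        rng = np.random.default_rng(12)
        n = 500
        lp = rng.normal(size=n) * 2.5
        times = rng.exponential(1 / (0.002 * np.exp(lp)))
        ids = [f"p{i}" for i in range(n)]
        samples = _surv_table(ids, times, np.ones(n, int))
        scores = pd.Series(lp, index=ids)
        auc = survival_roc(scores, samples, horizon=float(np.median(times)))
        assert auc > 0.9
        # independent estimator: with no censoring the IPCW cumulative/dynamic
        # AUC reduces to the same empirical quantity
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        y = Surv.from_arrays(np.ones(n, bool), times)
        ref, _ = cumulative_dynamic_auc(y, y, lp, [float(np.median(times))])
        assert auc == pytest.approx(float(ref[0]), abs=0.02)

    def test_score_reversal_flips_auc(self):
        rng = np.random.default_rng(13)
        n = 200
        lp = rng.normal(size=n)
        times = rng.exponential(1 / (0.003 * np.exp(lp)))
        ids = [f"p{i}" for i in range(n)]
        samples = _surv_table(ids, times, np.ones(n, int))
        horizon = float(np.median(times))
        a = survival_roc(pd.Series(lp, index=ids), samples, horizon)
        b = survival_roc(pd.Series(-lp, index=ids), samples, horizon)
        assert a + b == pytest.approx(1.0, abs=0.02)


class TestParameterRecovery:
    def test_known_linear_predictor_recovered(self):
        truth = np.array([-0.8, 0.6, -0.7, 0.5])
        good = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(500 + seed)
            vals = 2.0 ** rng.normal(7, 1, size=(4, 500))
            expr = ExpressionMatrix(
                [f"g{i}" for i in range(4)], [f"p{j}" for j in range(500)], vals
            )
            surv = simulate_survival(expr, truth, np.log(2) / 600, 0.3, seed=seed)
            samples = _surv_table(
                list(surv["sample_id"]), surv["os_days"], surv["os_event"]
            )
            log_expr = ExpressionMatrix(
                expr.feature_ids, expr.sample_ids, np.log2(expr.values + 1)
            )
            model = cox_multivariate_fit(log_expr, samples, alpha=1.01)
            est = model.coefficients
            rel = np.abs(est - truth) / np.abs(truth)
            good += (np.sign(est) == np.sign(truth)).all() and (rel < 0.3).all()
        assert good >= 0.9 * n_rep
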