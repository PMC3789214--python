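import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats
from sklearn import metrics as skm

from eegdx.classify import (
    ElasticNetConfig, GeneticSearchConfig, LogisticIndexModel, fit_elastic_net,
    fit_logistic, genetic_search, half_split_cv, metrics_from_counts,
    monte_carlo_thresholds, outcome_metrics, predict, single_biomarker_mcc,
)
from eegdx.signal_core import InvalidArgumentError


class TestFitLogistic:
    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(5), np.ones(5)][:, None]
        y = np.r_[np.zeros(5), np.ones(5)].astype(int)
        model = fit_logistic(x, y)
        assert model.separated
        _, cls = predict(model, x)
        assert np.array_equal(cls, y)

    def test_uninformative_features_give_prevalence_intercept(self, rng):
        x = rng.standard_normal((400, 2))
        y = (rng.random(400) < 0.25).astype(int)
        model = fit_logistic(x, y)
        prevalence = y.mean()
        assert model.beta0 == pytest.approx(np.log(prevalence / (1 - prevalence)),
                                            abs=0.3)
        assert np.all(np.abs(model.betas) < 0.3)

    def test_coefficient_recovery_within_wald_intervals(self, rng):
        """Estimates from data simulated at known (beta0, beta1) fall inside
        the 95% Wald interval in >=90% of replicates."""
        import statsmodels.api as sm

        beta0, beta1 = -0.5, 1.2
        hits = np.zeros(2)
        n_rep = 200
        for _ in range(n_rep):
            x = rng.standard_normal(120)
            p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
            y = (rng.random(120) < p).astype(int)
            if np.unique(y).size < 2 or np.bincount(y).min() < 2:
                continue
            model = fit_logistic(x[:, None], y)
            res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            se = res.bse
            hits += np.array([abs(model.beta0 - beta0) <= 1.96 * se[0],
                              abs(model.betas[0] - beta1) <= 1.96 * se[1]])
        assert np.all(hits / n_rep >= 0.9)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_logistic(np.ones((4, 1)), [1, 1, 1, 1])


class TestPredict:
    def test_boundary_probability_is_converter(self):
        model = LogisticIndexModel(beta0=0.0, betas=np.array([0.0]),
                                   biomarker_names=["x"])
        prob, cls = predict(model, np.array([[1.0]]))
        assert prob[0] == 0.5 and cls[0] == 1

    def test_closed_form_probability(self):
        model = LogisticIndexModel(beta0=0.0, betas=np.array([1.0]),
                                   biomarker_names=["x"])
        prob, _ = predict(model, np.array([[np.log(3.0)]]))
        assert prob[0] == pytest.approx(0.75)

    def test_missing_feature_rejected(self):
        model = LogisticIndexModel(beta0=0.0, betas=np.array([1.0]),
                                   biomarker_names=["x"])
        with pytest.raises(InvalidArgumentError):
            predict(model, pd.DataFrame({"y": [1.0]}))


class TestOutcomeMetrics:
    def test_heldout_elastic_net_worked_example(self):
        """SE 75% of 8 and SP 86% of 22 -> MCC 0.59, PLR 5.5, PPV 67%."""
        m = metrics_from_counts(tp=6, fp=3, tn=19, fn=2)
        assert m.sensitivity * 100 == pytest.approx(75, abs=0.5)
        assert m.specificity * 100 == pytest.approx(86, abs=0.5)
        assert m.positive_predictive_value * 100 == pytest.approx(67, abs=0.5)
        assert m.matthews_correlation == pytest.approx(0.59, abs=0.005)
        assert m.positive_likelihood_ratio == pytest.approx(5.5, abs=0.05)

    def test_perfect_classification_identities(self):
        y = np.r_[np.ones(8), np.zeros(22)].astype(int)
        m = outcome_metrics(y, y)
        assert (m.sensitivity, m.specificity, m.positive_predictive_value) == \
            (1.0, 1.0, 1.0)
        assert m.matthews_correlation == 1.0
        assert np.isinf(m.positive_likelihood_ratio)

    def test_inverted_prediction_anticorrelates(self):
        y = np.r_[np.ones(8), np.zeros(22)].astype(int)
        assert outcome_metrics(1 - y, y).matthews_correlation == -1.0

    def test_identities_on_random_confusion_matrices(self, rng):
        """MCC/SE/SP/PPV match the independent sklearn implementations."""
        for _ in range(300):
            y = rng.integers(0, 2, 30)
            yhat = rng.integers(0, 2, 30)
            if np.unique(y).size < 2:
                continue
            m = outcome_metrics(yhat, y)
            assert m.matthews_correlation == pytest.approx(
                skm.matthews_corrcoef(y, yhat), abs=1e-12)
            assert m.sensitivity == pytest.approx(
                skm.recall_score(y, yhat, zero_division=np.nan), nan_ok=True)
            assert m.specificity == pytest.approx(
                skm.recall_score(1 - y, 1 - yhat, zero_division=np.nan),
                nan_ok=True)


def planted_features(rng, n=34, n_noise=50, separation=4.0):
    X = pd.DataFrame(rng.standard_normal((n, n_noise)),
                     columns=[f"noise_{i}" for i in range(n_noise)])
    y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)].astype(int)
    X["planted"] = y * separation + 0.1 * rng.standard_normal(n)
    return X, y


class TestGeneticSearch:
    def test_zero_generations_returns_seed_set(self, rng):
        X, y = planted_features(rng)
        cfg = GeneticSearchConfig(n_generations=0, seed=0)
        selected, _, trace = genetic_search(X, y, cfg)
        ranking = single_biomarker_mcc(X, y)
        assert set(selected) == set(ranking.index[:5])
        assert len(trace) == 1

    def test_criterion_trace_non_decreasing(self, rng):
        X, y = planted_features(rng, separation=1.0)
        cfg = GeneticSearchConfig(n_generations=15, seed=3)
        _, _, trace = genetic_search(X, y, cfg)
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_planted_biomarker_recovery(self, rng):
        """A perfectly separating biomarker among 50 noise biomarkers is
        recovered (maximum achievable training PLR) in >=95% of 20 runs."""
        hits = 0
        for k in range(20):
            X, y = planted_features(np.random.default_rng(k))
            cfg = GeneticSearchConfig(n_generations=10, seed=k)
            selected, model, trace = genetic_search(X, y, cfg)
            _, cls = predict(model, X[selected] if hasattr(model, "b") else X[list(selected)])
            hits += np.isinf(trace[-1])  # PLR sentinel: SP=1, SE>0
        assert hits / 20 >= 0.95


class TestElasticNet:
    def test_pure_ridge_limit_keeps_all_features(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 8)),
                         columns=[f"f{i}" for i in range(8)])
        y = (X["f0"] + 0.5 * rng.standard_normal(60) > 0).astype(int)
        cfg = ElasticNetConfig(alpha=1.0, seed=0, n_lambdas=20)
        selected, model = fit_elastic_net(X, y, cfg)
        assert len(selected) == 8
        assert np.all(model.betas != 0)

    def test_max_penalty_empty_selection(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        cfg = ElasticNetConfig(alpha=0.8, seed=0, n_lambdas=1)
        selected, model = fit_elastic_net(X, y, cfg)
        assert selected == []

    def test_informative_features_recovered(self, rng):
        """3 informative features among 30 noise are all selected in >=90%
        of replicates at n=150."""
        hits = 0
        n_rep = 10
        for k in range(n_rep):
            r = np.random.default_rng(100 + k)
            X = pd.DataFrame(r.standard_normal((150, 33)),
                             columns=[f"f{i}" for i in range(33)])
            z = 1.5 * (X["f0"] + X["f1"] - X["f2"])
            y = (r.random(150) < 1 / (1 + np.exp(-z))).astype(int)
            cfg = ElasticNetConfig(alpha=0.8, seed=k, n_lambdas=25)
            selected, _ = fit_elastic_net(X, y, cfg)
            hits += {"f0", "f1", "f2"} <= set(selected)
        assert hits / n_rep >= 0.9

    def test_zero_variance_feature_dropped(self, rng):
        X = pd.DataFrame({"f0": rng.standard_normal(40),
                          "dead": np.ones(40)})
        y = (X["f0"] > 0).astype(int)
        with pytest.warns(UserWarning, match="zero-variance"):
            selected, model = fit_elastic_net(X, y, ElasticNetConfig(seed=0))
        assert "dead" not in model.biomarker_names


class TestMonteCarloThresholds:
    def test_study_scale_critical_values(self):
        """n=65 with 25 positives: MCC ~0.20 and PLR ~1.6 at the 95% level."""
        thr = monte_carlo_thresholds(65, 25, n_iterations=5000, seed=42)
        assert round(thr["MCC"], 2) == pytest.approx(0.20, abs=0.03)
        assert round(thr["PLR"], 1) == pytest.approx(1.6, abs=0.2)

    def test_asymptotic_normal_limit(self):
        """For large n the MCC critical value approaches 1.645/sqrt(n)."""
        n = 4000
        thr = monte_carlo_thresholds(n, 1500, n_iterations=2000, seed=7)
        assert thr["MCC"] == pytest.approx(1.645 / np.sqrt(n), abs=0.006)


class TestHalfSplitCV:
    def test_separable_feature_perfect_median(self, rng):
        X = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10) * 5]})
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        out = half_split_cv(X, y, n_iterations=50, seed=0)
        assert out["MCC"] == pytest.approx(1.0)

    def test_noise_features_near_zero(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        out = half_split_cv(X, y, n_iterations=100, seed=1)
        assert abs(out["MCC"]) < 0.25

    def test_deterministic_under_seed(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=list("ab"))
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        a = half_split_cv(X, y, n_iterations=50, seed=5)
        b = half_split_cv(X, y, n_iterations=50, seed=5)
        assert a == b
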