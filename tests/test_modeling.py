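"""Preprocessing chain, classifier closed forms, ROC and the 0.632 bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rimmune.modeling import (
    MODEL_ROSTER,
    ModelSpec,
    ResampleEstimate,
    _HandLDA,
    _HandNB,
    bootstrap632_evaluate,
    bootstrap632_evaluate_roster,
    fit_predict,
    lda_group_means,
    preprocess_fit,
    preprocess_transform,
    roc_auc,
    select_final_model,
    yeo_johnson,
    youden_threshold,
)

LDA_SPEC = next(m for m in MODEL_ROSTER if m.name == "LDA")


class TestYeoJohnson:
    @given(st.floats(-50.0, 50.0))
    def test_lambda_one_is_identity(self, x):
        assert yeo_johnson(x, 1.0) == pytest.approx(x, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("lam", [-1.0, 0.0, 0.5, 1.0, 2.0, 3.0])
    def test_zero_maps_to_zero(self, lam):
        assert yeo_johnson(0.0, lam) == 0.0

    def test_log_branch(self):
        assert yeo_johnson(3.0, 0.0) == pytest.approx(np.log(4.0))
        assert yeo_johnson(-3.0, 2.0) == pytest.approx(-np.log(4.0))

    def test_monotone_and_continuous_across_zero(self):
        for lam in (-0.5, 0.0, 0.7, 2.0, 2.5):
            x = np.linspace(-5, 5, 201)
            y = yeo_johnson(x, lam)
            assert np.all(np.diff(y) > 0)


class TestPreprocess:
    def test_chain_removes_constants_imputes_and_standardizes(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "const": np.full(20, 3.0),
                "a": rng.lognormal(size=20),
                "b": rng.normal(size=20),
            }
        )
        df.loc[3, "a"] = np.nan
        state = preprocess_fit(df, k_neighbors=3)
        assert "const" not in state.retained
        x = preprocess_transform(state, df)
        assert np.abs(x.mean(axis=0)).max() < 1e-8
        assert np.abs(x.std(axis=0) - 1).max() < 1e-8

    def test_knn_one_neighbor_copies_nearest(self):
        df = pd.DataFrame({"a": [0.0, 10.0, np.nan], "b": [0.0, 10.0, 9.5]})
        state = preprocess_fit(df, k_neighbors=1)
        filled = state.imputer.transform(df[state.retained].to_numpy())
        assert filled[2, list(state.retained).index("a")] == pytest.approx(10.0)

    def test_all_constant_table_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            preprocess_fit(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))


class TestClassifiers:
    def test_one_dimensional_lda_boundary_at_midpoint(self):
        x = np.array([[-1.2], [-0.8], [-1.0], [0.8], [1.2], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = _HandLDA().fit(x, y)
        assert m.decision_function(np.array([[0.0]]))[0] == pytest.approx(0.0, abs=1e-9)
        assert m.decision_function(np.array([[0.5]]))[0] > 0

    def test_separable_toy_set_perfectly_classified(self):
        rng = np.random.default_rng(1)
        x0 = rng.normal(loc=(-3, -3), scale=0.3, size=(20, 2))
        x1 = rng.normal(loc=(3, 3), scale=0.3, size=(20, 2))
        x = np.vstack([x0, x1])
        y = np.repeat([0, 1], 20)
        scores, labels = fit_predict(LDA_SPEC, (x, y), x)
        assert (labels == y).all()

    def test_lda_posterior_equals_bayes_rule_with_fitted_gaussians(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 2))
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        m = _HandLDA().fit(x, y)
        # brute-force Bayes: shared-covariance Gaussian densities
        x0, x1 = x[y == 0], x[y == 1]
        cov = ((x0 - x0.mean(0)).T @ (x0 - x0.mean(0)) + (x1 - x1.mean(0)).T @ (x1 - x1.mean(0))) / 8
        icov = np.linalg.inv(cov)

        def logd(p, mu):
            d = p - mu
            return -0.5 * d @ icov @ d

        for p in x:
            direct = (logd(p, x1.mean(0)) + np.log(0.5)) - (logd(p, x0.mean(0)) + np.log(0.5))
            assert m.decision_function(p[None, :])[0] == pytest.approx(direct, abs=1e-9)

    def test_naive_bayes_matches_independent_gaussian_arithmetic(self):
        x = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = _HandNB().fit(x, y)
        s = m.decision_function(np.array([[1.0], [11.0]]))
        assert s[0] < 0 < s[1]

    def test_singular_covariance_is_ridge_regularized(self):
        # p > n forces the ridge path; scores must still be finite and ordered
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 30))
        x[:5] += 2.0
        y = np.repeat([1, 0], 5)
        m = _HandLDA().fit(x, y)
        s = m.decision_function(x)
        assert np.isfinite(s).all()
        assert s[:5].mean() > s[5:].mean()


class TestRoc:
    def test_enumerated_two_by_two_fixture(self):
        # positives {0.9, 0.8}, negatives {0.7, 0.85}: 3 of 4 pairs won
        scores = np.array([0.9, 0.8, 0.7, 0.85])
        labels = np.array([1, 1, 0, 0])
        auc, p = roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)
        assert 0 < p <= 1

    def test_perfect_separation(self):
        auc, _ = roc_auc(np.array([3.0, 2.0, 1.0, 0.0]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, p = roc_auc(np.ones(8), np.repeat([0, 1], 4))
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    @given(st.integers(0, 1000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, size=20)
        if labels.sum() in (0, 20):
            return
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_youden_threshold_separates_separable_scores(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        thr = youden_threshold(scores, labels)
        assert 0.3 <= thr < 0.8


def _toy_cohort(n=60, p=8, signal=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    x = rng.normal(size=(n, p))
    x[:, 0] += signal * y
    x[:, 1] -= signal * y
    return pd.DataFrame(x, columns=[f"f{i}" for i in range(p)]), y


class TestBootstrap632:
    def test_informative_features_score_high_with_valid_sds(self):
        table, y = _toy_cohort(signal=2.0, seed=1)
        est = bootstrap632_evaluate(LDA_SPEC, table, y, B=10, seed=2)
        assert est.auc > 0.85
        assert est.auc_sd >= 0 and est.sens_sd >= 0 and est.spec_sd >= 0
        assert 0 <= est.sens <= 1 and 0 <= est.spec <= 1
        assert est.n_used <= 10

    def test_null_features_score_near_half(self):
        table, y = _toy_cohort(signal=0.0, seed=3)
        est = bootstrap632_evaluate(LDA_SPEC, table, y, B=10, seed=4)
        assert 0.3 < est.auc < 0.7

    def test_deterministic_given_seed(self):
        table, y = _toy_cohort(seed=5)
        a = bootstrap632_evaluate(LDA_SPEC, table, y, B=5, seed=6)
        b = bootstrap632_evaluate(LDA_SPEC, table, y, B=5, seed=6)
        assert (a.auc, a.sens, a.spec) == (b.auc, b.sens, b.spec)

    def test_no_leakage_preprocessing_refit_per_resample(self):
        # resample preprocessing statistics must differ from full-data stats
        table, y = _toy_cohort(seed=7)
        full = preprocess_fit(table)
        rng = np.random.default_rng(8)
        idx = rng.integers(0, len(table), size=len(table))
        boot = preprocess_fit(table.iloc[idx])
        assert not np.allclose(full.center, boot.center)

    def test_roster_shares_resamples_and_returns_all_models(self):
        table, y = _toy_cohort(seed=9)
        out = bootstrap632_evaluate_roster(MODEL_ROSTER, table, y, B=4, seed=10)
        assert set(out) == {m.name for m in MODEL_ROSTER}
        single = bootstrap632_evaluate(LDA_SPEC, table, y, B=4, seed=10)
        assert single.auc == pytest.approx(out["LDA"].auc)

    def test_b_below_two_rejected(self):
        table, y = _toy_cohort()
        with pytest.raises(ValueError, match="B"):
            bootstrap632_evaluate(LDA_SPEC, table, y, B=1, seed=0)


class TestSelection:
    def _est(self, model, auc, sd=0.0):
        return ResampleEstimate(model, auc, 0.5, 0.5, sd, 0.0, 0.0, B=25, seed=0)

    def test_single_model_returned_unchanged(self):
        spec = select_final_model([self._est("random_forest", 0.9, 0.1)])
        assert spec.name == "random_forest"

    def test_simpler_model_within_one_sd_wins(self):
        ests = [self._est("random_forest", 0.795, 0.108), self._est("LDA", 0.772, 0.090)]
        assert select_final_model(ests).name == "LDA"

    def test_linear_model_trailing_by_more_than_one_sd_loses(self):
        ests = [self._est("random_forest", 0.90, 0.02), self._est("LDA", 0.70, 0.05)]
        assert select_final_model(ests).name == "random_forest"

    def test_empty_estimates_rejected(self):
        with pytest.raises(ValueError):
            select_final_model([])

    def test_complexity_ranks_put_linear_models_below_ensembles(self):
        ranks = {m.name: m.complexity_rank for m in MODEL_ROSTER}
        for linear in ("LDA", "naive_bayes", "penalized_logistic"):
            for ensemble in ("bagged_CART", "random_forest"):
                assert ranks[linear] < ranks[ensemble]


class TestGroupMeans:
    def test_balanced_classes_mirror_and_centering_identity(self):
        table, y = _toy_cohort(n=40, seed=11)
        y = np.repeat([0, 1], 20)  # balanced
        rep = lda_group_means(table, y, ["f0", "f1"]).table
        n_low, n_high = 20, 20
        for c in rep.columns:
            assert n_low * rep.loc["low", c] + n_high * rep.loc["high", c] == pytest.approx(
                0.0, abs=1e-8
            )
            assert rep.loc["low", c] == pytest.approx(-rep.loc["high", c], abs=1e-8)

    def test_signal_direction_appears_in_group_means(self):
        table, y = _toy_cohort(n=60, signal=2.0, seed=12)
        rep = lda_group_means(table, y, ["f0", "f1"]).table
        assert rep.loc["high", "f0"] > 0 > rep.loc["low", "f0"]
        assert rep.loc["high", "f1"] < 0 < rep.loc["low", "f1"]

    def test_unknown_predictor_rejected(self):
        table, y = _toy_cohort()
        with pytest.raises(KeyError):
            lda_group_means(table, y, ["nope"])
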