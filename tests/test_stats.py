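import itertools
import json

import numpy as np
import pandas as pd
import pytest

from aptasl import (
    GroupFeatureParams,
    cohort_summary,
    fit_logistic,
    generate_feature_cohort,
    lasso_select,
    mann_whitney_u,
    roc_analysis,
    run_full_analysis,
    screen_features,
)
from aptasl.stats import SeparationError


def exact_mwu_p(x, y):
    """Two-sided p by full enumeration of group labelings (oracle)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pooled.argsort().argsort() + 1.0  # no ties assumed
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    dist = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        dist.append(u)
    dist = np.asarray(dist)
    mean = n1 * (len(pooled) - n1) / 2
    # two-sided: as or more extreme in distance from the null mean
    return np.mean(np.abs(dist - mean) >= np.abs(u_obs - mean) - 1e-12)


class TestMannWhitney:
    def test_no_overlap_example(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_mwu_p([1, 2, 3], [4, 5, 6]))

    def test_identical_multisets_p_one(self):
        res = mann_whitney_u([1, 2], [1, 2])
        assert res.p_value == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        base = mann_whitney_u(x, y)
        warped = mann_whitney_u(np.exp(x), np.exp(y))
        assert base.p_value == pytest.approx(warped.p_value)
        assert base.u == warped.u

    def test_all_tied_degenerate(self):
        res = mann_whitney_u([3.0, 3.0, 3.0], [3.0, 3.0])
        assert res.p_value == 1.0
        assert res.method == "degenerate"

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(1, 8))
            n2 = int(rng.integers(1, 8))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_mwu_p(x, y), abs=1e-12)

    def test_exact_vs_asymptotic_agreement_n8(self, rng):
        from scipy.stats import mannwhitneyu

        diffs = []
        for _ in range(50):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            approx = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            diffs.append(abs(exact - approx))
        # the continuity-corrected normal approximation tracks the exact
        # null distribution to ~0.01 at n=8; worst single draws can reach
        # slightly beyond that discretization step
        assert np.mean(diffs) < 0.01
        assert max(diffs) < 0.02


class TestScreening:
    def cohort(self, rng, delta=0.0, n0=18, n1=40):
        return pd.DataFrame({
            "outcome": [0] * n0 + [1] * n1,
            "rASL_mean": np.concatenate([rng.normal(0, 1, n0), rng.normal(delta, 1, n1)]),
            "rAPT_mean": rng.normal(0, 1, n0 + n1),
        })

    def test_identical_feature_not_flagged(self, rng):
        df = self.cohort(rng)
        df["rAPT_mean"] = 1.0
        res = {r.feature: r for r in screen_features(df)}
        assert not res["rAPT_mean"].significant
        assert res["rAPT_mean"].p_value == 1.0

    def test_alpha_zero_flags_nothing(self, rng):
        df = self.cohort(rng, delta=5.0)
        assert not any(r.significant for r in screen_features(df, alpha=0.0))

    def test_strong_shift_flagged(self, rng):
        df = self.cohort(rng, delta=3.0)
        res = {r.feature: r for r in screen_features(df)}
        assert res["rASL_mean"].significant

    def test_single_class_rejected(self, rng):
        df = self.cohort(rng)
        df["outcome"] = 0
        with pytest.raises(ValueError, match="two outcome classes"):
            screen_features(df)


def signal_cohort(seed=0, n0=20, n1=40, d=2.0, p_noise=9):
    rng = np.random.default_rng(seed)
    data = {"outcome": [0] * n0 + [1] * n1}
    data["rASL_signal"] = np.concatenate(
        [rng.normal(0, 1, n0), rng.normal(d, 1, n1)]
    )
    for j in range(p_noise):
        data[f"rAPT_noise{j}"] = rng.normal(0, 1, n0 + n1)
    return pd.DataFrame(data)


class TestLasso:
    def test_max_lambda_empty_active_set(self):
        df = signal_cohort(seed=1)
        feats = [c for c in df.columns if c != "outcome"]
        sel = lasso_select(df, feats, n_folds=5, seed=0)
        assert sel.active_path[0] == 0  # path starts at lambda_max

    def test_active_set_monotone_along_path(self):
        df = signal_cohort(seed=2)
        feats = [c for c in df.columns if c != "outcome"]
        sel = lasso_select(df, feats, n_folds=5, seed=0)
        # path is stored descending in lambda: active size non-decreasing
        assert all(a <= b for a, b in zip(sel.active_path, sel.active_path[1:]))

    def test_strong_feature_selected_in_most_seeds(self):
        hits = 0
        for seed in range(10):
            df = signal_cohort(seed=seed)
            feats = [c for c in df.columns if c != "outcome"]
            sel = lasso_select(df, feats, n_folds=5, seed=seed)
            hits += "rASL_signal" in sel.selected
        assert hits >= 9

    def test_duplicated_feature_does_not_worsen_cv_deviance(self):
        df = signal_cohort(seed=3)
        feats = [c for c in df.columns if c != "outcome"]
        base = lasso_select(df, feats, n_folds=5, seed=0)
        df2 = df.copy()
        df2["rASL_signal_copy"] = df2["rASL_signal"]
        dup = lasso_select(df2, feats + ["rASL_signal_copy"], n_folds=5, seed=0)
        assert dup.cv_deviance.min() <= base.cv_deviance.min() + 1e-6

    def test_too_few_candidates_rejected(self):
        df = signal_cohort()
        with pytest.raises(ValueError, match="at least 2"):
            lasso_select(df, ["rASL_signal"])

    def test_folds_exceeding_minority_class_rejected(self):
        df = signal_cohort(n0=4, n1=40)
        feats = [c for c in df.columns if c != "outcome"]
        with pytest.raises(ValueError, match="stratify"):
            lasso_select(df, feats, n_folds=10)

    def test_reproducible_given_seed(self):
        df = signal_cohort(seed=4)
        feats = [c for c in df.columns if c != "outcome"]
        a = lasso_select(df, feats, n_folds=5, seed=11)
        b = lasso_select(df, feats, n_folds=5, seed=11)
        assert a.selected == b.selected
        assert a.chosen_lambda == b.chosen_lambda
        assert np.array_equal(a.cv_deviance, b.cv_deviance)


class TestLogistic:
    def test_constant_zero_feature_gives_null_model(self):
        df = pd.DataFrame({"outcome": [0, 1] * 10, "f": 0.0})
        model = fit_logistic(df, ["f"])
        assert model.intercept == pytest.approx(0.0, abs=1e-8)
        assert model.coefficients["f"] == 0.0
        probs = 1 / (1 + np.exp(-model.scores))
        assert np.allclose(probs, 0.5, atol=1e-8)

    def test_complete_separation_raises(self):
        df = pd.DataFrame({"outcome": [0] * 10 + [1] * 10,
                           "f": np.r_[np.arange(10), np.arange(100, 110)].astype(float)})
        with pytest.raises(SeparationError, match="separation"):
            fit_logistic(df, ["f"])

    def test_ridge_fallback_flagged(self):
        df = pd.DataFrame({"outcome": [0] * 10 + [1] * 10,
                           "f": np.r_[np.arange(10), np.arange(100, 110)].astype(float)})
        model = fit_logistic(df, ["f"], ridge_eps=1e-3)
        assert model.penalized
        assert model.coefficients["f"] > 0

    def test_single_feature_score_has_same_roc_as_raw_feature(self, rng):
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        f = rng.normal(y.astype(float), 1.0)
        df = pd.DataFrame({"outcome": y, "f": f})
        model = fit_logistic(df, ["f"])
        auc_score = roc_analysis(model.scores, y).auc
        auc_raw = roc_analysis(f, y).auc
        assert auc_score == pytest.approx(auc_raw, abs=1e-12)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1.0, 2.0, 10.0, 11.0], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_pair_counting_example(self):
        # positives {0.9, 0.8}, negatives {0.7, 0.85}: 3 of 4 pairs won
        res = roc_analysis([0.9, 0.8, 0.7, 0.85], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)

    def test_all_tied_scores(self):
        res = roc_analysis([1.0] * 6, [0, 0, 0, 1, 1, 1])
        assert res.auc == pytest.approx(0.5)

    def test_orientation_flip(self, rng):
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        s = -y + rng.normal(0, 0.3, 40)  # lower score = positive
        res = roc_analysis(s, y)
        assert res.direction == "lower"
        assert res.auc >= 0.5
        assert res.auc_raw == pytest.approx(1 - res.auc)

    def test_auc_raw_complementarity(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.normal(size=30)
        a = roc_analysis(s, y).auc_raw
        b = roc_analysis(-s, y).auc_raw
        assert a + b == pytest.approx(1.0)

    def test_auc_equals_u_over_n1n2(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 25)
            y[:2] = [0, 1]
            s = np.round(rng.normal(size=25), 1)  # force ties
            res = roc_analysis(s, y)
            u = mann_whitney_u(s[y == 1], s[y == 0]).u
            assert res.auc_raw == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_ci_contains_auc_and_se_positive(self, rng):
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        s = rng.normal(y.astype(float), 1.0)
        res = roc_analysis(s, y)
        assert 0.0 <= res.ci[0] <= res.auc <= res.ci[1] <= 1.0
        assert res.se > 0

    def test_cutoff_rules(self, rng):
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        s = rng.normal(y.astype(float), 0.8)
        youden = roc_analysis(s, y, cutoff_rule="youden")
        closest = roc_analysis(s, y, cutoff_rule="closest01")
        assert 0 <= youden.sensitivity <= 100 and 0 <= youden.specificity <= 100
        assert 0 <= closest.sensitivity <= 100 and 0 <= closest.specificity <= 100

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_analysis([1.0, 2.0], [1, 1])


class TestFullAnalysis:
    def test_deterministic_given_seed(self):
        coh = generate_feature_cohort(GroupFeatureParams(), seed=5)
        a = run_full_analysis(coh, seed=5, ridge_eps=1e-6)
        b = run_full_analysis(coh, seed=5, ridge_eps=1e-6)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_zero_signal_cohort_usually_empty(self, null_group_params):
        coh = generate_feature_cohort(null_group_params, seed=17)
        rep = run_full_analysis(coh, seed=17, ridge_eps=1e-6)
        # under the null, ~1 of 20 features flags at alpha=0.05
        assert len(rep["significant_features"]) <= 4

    def test_signal_cohort_produces_combination_roc(self):
        coh = generate_feature_cohort(GroupFeatureParams(), seed=2)
        rep = run_full_analysis(coh, seed=2, ridge_eps=1e-6)
        variables = [r["variable"] for r in rep["roc_table"]]
        assert "combination" in variables
        assert rep["model"] is not None
        assert set(rep["selected_features"]) <= set(rep["significant_features"])

    def test_group_summary_matches_cohort(self):
        coh = generate_feature_cohort(GroupFeatureParams(), seed=3)
        rep = run_full_analysis(coh, seed=3, ridge_eps=1e-6)
        row = next(r for r in rep["group_summary"] if r["feature"] == "rASL_mean")
        fav = coh.loc[coh.outcome == 0, "rASL_mean"]
        assert row["mean_favorable"] == pytest.approx(fav.mean())
        assert row["sd_favorable"] == pytest.approx(fav.std(ddof=1))

    def test_bad_lasso_on_rejected(self):
        coh = generate_feature_cohort(GroupFeatureParams(), seed=1)
        with pytest.raises(ValueError, match="lasso_on"):
            run_full_analysis(coh, lasso_on="everything")


class TestCohortSummary:
    def build(self, n=58, k_hyp=53):
        return pd.DataFrame({
            "outcome": [0] * 18 + [1] * (n - 18),
            "hypertension": [1] * k_hyp + [0] * (n - k_hyp),
            "sex": ["M"] * 43 + ["F"] * (n - 43),
            "age": np.linspace(40, 80, n),
        })

    def test_percent_two_decimals(self):
        s = cohort_summary(self.build(), categorical=("hypertension",), continuous=("age",))
        assert s["variables"]["hypertension"]["overall_percent"] == 91.38
        assert s["variables"]["hypertension"]["overall_count"] == 53
        assert s["n_total"] == 58

    def test_zero_prevalence(self):
        s = cohort_summary(self.build(k_hyp=0), categorical=("hypertension",), continuous=())
        assert s["variables"]["hypertension"]["overall_percent"] == 0.0

    def test_missing_covariate_warns_and_skips(self):
        df = self.build().drop(columns=["age"])
        with pytest.warns(UserWarning, match="age"):
            s = cohort_summary(df, categorical=("hypertension",), continuous=("age",))
        assert "age" not in s["variables"]

    def test_continuous_uses_mwu(self):
        s = cohort_summary(self.build(), categorical=(), continuous=("age",))
        assert 0 < s["variables"]["age"]["p_value"] <= 1

    def test_group_sizes(self):
        s = cohort_summary(self.build(), categorical=(), continuous=())
        assert s["group_sizes"] == {"0": 18, "1": 40}
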