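"""Interaction GLM, exact tests, power analysis and classifier validation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ymaze.stats import (
    anova_two_way, chisq_power_n, cohens_w, compare_distributions,
    fisher_2x2, fit_strategy_glm, holdout_validate, loo_validate,
    mann_whitney, second_difference, train_altitude_classifier,
    wilcoxon_signed,
)

AGES = ("children", "young", "older")
CONDS = ("landmark", "geometry")


def _cohort(cells, n=10):
    """CohortTable with exact per-cell allocentric counts."""
    rows = []
    for (age, cond), k in cells.items():
        for i in range(n):
            rows.append(dict(subject_id=f"{age}_{cond}_{i}", age_group=age,
                             condition=cond,
                             allocentric_majority=int(i < k)))
    return pd.DataFrame(rows)


class TestStrategyGLM:
    def test_saturated_fit_equals_cell_proportions(self):
        cells = {(a, c): k for (a, c), k in zip(
            itertools.product(AGES, CONDS), [3, 8, 9, 2, 4, 7])}
        fit = fit_strategy_glm(_cohort(cells))
        for cell, k in cells.items():
            assert fit.cell_probabilities[cell] == pytest.approx(k / 10)
        assert not fit.separation

    def test_separated_cell_reports_raw_proportion(self):
        cells = {(a, c): 10 for (a, c) in itertools.product(AGES, CONDS)}
        cells[("children", "landmark")] = 4
        fit = fit_strategy_glm(_cohort(cells))
        assert fit.separation
        assert fit.cell_probabilities[("young", "geometry")] == 1.0
        assert fit.cell_probabilities[("children", "landmark")] == 0.4

    def test_empty_cell_rejected(self):
        cells = {(a, c): 5 for (a, c) in itertools.product(AGES, CONDS)}
        df = _cohort(cells)
        df = df[~((df.age_group == "older") & (df.condition == "geometry"))]
        with pytest.raises(ValueError):
            fit_strategy_glm(df)

    def test_sampled_cohort_probabilities_match_proportions(self, rng):
        rows = []
        gen = {(a, c): p for (a, c), p in zip(
            itertools.product(AGES, CONDS), [0.3, 0.8, 0.9, 0.99, 0.3, 0.8])}
        for (a, c), p in gen.items():
            k = rng.binomial(1, p, size=40)
            for i, v in enumerate(k):
                rows.append(dict(subject_id=f"{a}{c}{i}", age_group=a,
                                 condition=c, allocentric_majority=int(v)))
        df = pd.DataFrame(rows)
        fit = fit_strategy_glm(df)
        obs = df.groupby(["age_group", "condition"]).allocentric_majority.mean()
        for cell, p in fit.cell_probabilities.items():
            assert p == pytest.approx(obs.loc[cell], abs=1e-12)


class TestSecondDifference:
    def test_rounded_study_cells_give_delta_039(self):
        """From cell probabilities (young 0.88 -> 0.99, children
        0.32 -> 0.82): (0.82 - 0.32) - (0.99 - 0.88) = 0.39."""
        cells = {("young", "landmark"): 88, ("young", "geometry"): 99,
                 ("children", "landmark"): 32, ("children", "geometry"): 82,
                 ("older", "landmark"): 31, ("older", "geometry"): 82}
        fit = fit_strategy_glm(_cohort(cells, n=100))
        est = second_difference(fit, ("children", "young"))
        assert est.delta == pytest.approx(0.39, abs=1e-12)
        assert est.p_value < 0.001

    def test_equal_condition_effects_give_zero(self):
        cells = {("young", "landmark"): 4, ("young", "geometry"): 6,
                 ("children", "landmark"): 2, ("children", "geometry"): 4,
                 ("older", "landmark"): 5, ("older", "geometry"): 7}
        fit = fit_strategy_glm(_cohort(cells))
        est = second_difference(fit, ("children", "young"))
        assert est.delta == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_in_group_order(self):
        cells = {(a, c): k for (a, c), k in zip(
            itertools.product(AGES, CONDS), [3, 8, 9, 10, 4, 7])}
        fit = fit_strategy_glm(_cohort(cells))
        a = second_difference(fit, ("children", "young"))
        b = second_difference(fit, ("young", "children"))
        assert a.delta == pytest.approx(-b.delta)
        assert a.se == pytest.approx(b.se)

    def test_unknown_group_rejected(self):
        cells = {(a, c): 5 for (a, c) in itertools.product(AGES, CONDS)}
        fit = fit_strategy_glm(_cohort(cells))
        with pytest.raises(ValueError):
            second_difference(fit, ("children", "adults"))


class TestFisher:
    def test_null_table(self):
        r = fisher_2x2([[5, 5], [5, 5]])
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.effect_size == pytest.approx(0.0)

    def test_diagonal_table_matches_enumeration(self):
        """Two-sided p of [[10,0],[0,10]] equals 2 / C(20,10) by direct
        hypergeometric enumeration."""
        r = fisher_2x2([[10, 0], [0, 10]])
        assert r.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_phi_equals_binary_pearson_correlation(self, rng):
        for _ in range(20):
            t = rng.integers(1, 12, size=(2, 2))
            r = fisher_2x2(t)
            x, y = [], []
            for i in range(2):
                for j in range(2):
                    x += [1 - i] * int(t[i, j])
                    y += [1 - j] * int(t[i, j])
            expect = np.corrcoef(x, y)[0, 1]
            assert r.effect_size == pytest.approx(expect, abs=1e-12)
            assert r.extra["cohens_w"] == pytest.approx(abs(expect))

    def test_one_sided_interval_shape(self):
        r = fisher_2x2([[9, 2], [3, 8]], alternative="greater")
        lo, hi = r.odds_ratio_ci
        assert hi == np.inf and 0 < lo < r.odds_ratio

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2([[0, 0], [3, 8]])


class TestPower:
    def test_study_parameters_give_77(self):
        assert chisq_power_n(0.356, 2, 0.05, 0.8) == 77

    def test_medium_effect_df1_gives_32(self):
        # numeric inversion oracle: lambda* ~ 7.849 at df=1 -> N = 32
        assert chisq_power_n(0.5, 1, 0.05, 0.8) == 32

    def test_returned_n_is_minimal(self):
        for w, df in [(0.356, 2), (0.5, 1), (0.2, 3)]:
            n = chisq_power_n(w, df)
            crit = sps.chi2.ppf(0.95, df)
            assert sps.ncx2.sf(crit, df, n * w * w) >= 0.8
            assert sps.ncx2.sf(crit, df, (n - 1) * w * w) < 0.8

    def test_monotone_in_effect_size(self):
        ns = [chisq_power_n(w, 2) for w in (0.2, 0.3, 0.356, 0.5, 0.8)]
        assert ns == sorted(ns, reverse=True)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            chisq_power_n(0.0, 2)
        with pytest.raises(ValueError):
            chisq_power_n(0.5, 2, alpha=1.2)


class TestRankTests:
    def test_identical_samples_are_null(self):
        x = np.arange(10.0)
        r = mann_whitney(x, x)
        assert r.p_value > 0.9
        assert abs(r.effect_size) < 0.05

    def test_fully_separated_samples_maximal_u(self):
        r = mann_whitney([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert r.statistic == 25.0
        # exact two-sided p from permutation enumeration: 2 / C(10,5)
        assert r.p_value == pytest.approx(2 / math.comb(10, 5), rel=1e-9)

    def test_degenerate_wilcoxon_flagged(self):
        r = wilcoxon_signed([0.0, 0.0, 0.0])
        assert r.extra.get("degenerate")
        assert r.p_value == 1.0

    def test_wilcoxon_shift_detected(self, rng):
        d = rng.normal(1.0, 0.5, size=30)
        r = wilcoxon_signed(d)
        assert r.p_value < 1e-4
        assert r.effect_size > 0.5

    def test_dispatch(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert compare_distributions(x, y, "mann_whitney").name == "U"
        assert compare_distributions(x, y, "wilcoxon").name == "W"
        with pytest.raises(ValueError):
            compare_distributions(x, y, "kruskal")


class TestAnova:
    def test_planted_interaction_detected(self, rng):
        rows = []
        for age in ("young", "older"):
            for cond in CONDS:
                mu = 5.0 + (3.0 if (age == "older" and cond == "landmark")
                            else 0.0)
                for v in rng.normal(mu, 1.0, size=25):
                    rows.append(dict(age_group=age, condition=cond, y=v))
        df = pd.DataFrame(rows)
        out = anova_two_way(df, "y", simple_effects="condition")
        assert out["age_group:condition"].p_value < 1e-4
        simple = out["simple:age_group@condition=landmark"]
        assert simple.p_value < 1e-4
        assert simple.extra["bonferroni_m"] == 2
        null_simple = out["simple:age_group@condition=geometry"]
        assert null_simple.p_value > 0.05

    def test_bonferroni_never_below_uncorrected(self, rng):
        rows = [dict(age_group=a, condition=c, y=v)
                for a in ("young", "older") for c in CONDS
                for v in rng.normal(0, 1, size=10)]
        out = anova_two_way(pd.DataFrame(rows), "y",
                            simple_effects="condition")
        for k, r in out.items():
            if k.startswith("simple:"):
                assert r.p_value >= r.extra["p_uncorrected"]


class TestClassifier:
    def test_separable_features_train_perfectly(self):
        x = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        y = np.array(["ego"] * 3 + ["allo"] * 3)
        clf = train_altitude_classifier(x, y)
        assert (clf.predict(x.reshape(-1, 1)) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_altitude_classifier([1.0, 2.0], ["a", "a"])

    def test_constant_feature_predicts_majority(self):
        x = np.zeros(10)
        y = np.array(["a"] * 7 + ["b"] * 3)
        clf = train_altitude_classifier(x, y)
        assert (clf.predict(x.reshape(-1, 1)) == "a").all()

    def test_gaussian_accuracy_matches_bayes_rate(self, rng):
        """Two unit-variance Gaussian classes separated by d have Bayes
        accuracy Phi(d/2); the trained classifier approaches it."""
        for d in (1.0, 2.0):
            n = 500
            x = np.concatenate([rng.normal(0, 1, n), rng.normal(d, 1, n)])
            y = np.array(["lo"] * n + ["hi"] * n)
            clf = train_altitude_classifier(x, y)
            acc = (clf.predict(x.reshape(-1, 1)) == y).mean()
            assert acc == pytest.approx(sps.norm.cdf(d / 2), abs=0.03)


class TestValidation:
    def test_separable_data_validate_perfectly(self):
        x = np.concatenate([np.zeros(8), np.ones(8) * 10])
        y = np.array(["a"] * 8 + ["b"] * 8)
        hv = holdout_validate(x, y, reps=50, seed=0)
        assert hv.overall_correct == 1.0
        assert hv.p_value == 0.0
        lv = loo_validate(x, y)
        assert lv.overall_correct == 1.0

    def test_holdout_fixed_seed_reproducible(self, rng):
        x = rng.normal(size=24)
        y = np.array(["a", "b"] * 12)
        a = holdout_validate(x, y, reps=40, seed=7)
        b = holdout_validate(x, y, reps=40, seed=7)
        assert np.array_equal(a.distribution, b.distribution)

    def test_chance_features_give_half_p_value(self, rng):
        """Labels independent of the feature: the below-chance probability
        averages ~0.5 over independent null datasets (within any one
        dataset its chance associations are learnable by both split
        halves, so the p-value is roughly uniform across datasets)."""
        ps, accs = [], []
        for k in range(20):
            n_cls = 500
            x = rng.normal(size=2 * n_cls)
            y = np.array(["a"] * n_cls + ["b"] * n_cls)
            hv = holdout_validate(x, y, reps=60, seed=int(rng.integers(1e6)))
            ps.append(hv.p_value)
            accs.append(hv.overall_correct)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.02)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.15)

    def test_loo_hand_enumerated_folds(self):
        """n = 4, features {0,0,1,1}: matching labels classify 4/4; the
        anti-matching labelling classifies 0/4 (each held-out point falls
        on the wrong side of the boundary fit to the remaining three)."""
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert loo_validate(x, ["a", "a", "b", "b"]).overall_correct == 1.0
        assert loo_validate(
            np.array([0.0, 1.0, 0.0, 1.0]),
            ["a", "a", "b", "b"]).overall_correct == 0.0

    def test_loo_invariant_to_ordering(self, rng):
        x = rng.normal(size=16)
        y = np.array(["a"] * 8 + ["b"] * 8)
        base = loo_validate(x, y).overall_correct
        perm = rng.permutation(16)
        assert loo_validate(x[perm], y[perm]).overall_correct \
            == pytest.approx(base)

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ValueError):
            loo_validate([1.0, 2.0], ["a", "b"])
        with pytest.raises(ValueError):
            holdout_validate([1.0, 2.0], ["a", "a"], reps=5)


class TestCohensW:
    def test_matches_chi2_definition(self, rng):
        t = rng.integers(2, 20, size=(3, 2))
        chi2 = sps.chi2_contingency(t, correction=False)[0]
        assert cohens_w(t) == pytest.approx(math.sqrt(chi2 / t.sum()))
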