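"""Statistical layer: interaction GLM, contingency and rank tests,
power analysis, and the gaze-altitude strategy classifier.

The central model is a binomial GLM (logit link) of the per-subject
majority-allocentric outcome on age group x condition with full
interaction. Because that design is saturated, the fitted cell
probabilities equal the observed cell proportions; interactions are
summarized as *second differences* on the probability scale,

    D(g1, g2) = [P(g1, geometry) - P(g1, landmark)]
              - [P(g2, geometry) - P(g2, landmark)],

the change, between conditions, of the between-group difference in
allocentric-response probability, with delta-method standard errors
(independent binomial cell variances under the saturated fit).

Effect sizes follow the study's conventions: phi and Cohen's w for
contingency tables, r = z / sqrt(N) for rank tests. The predictive model
is a single-predictor logistic classifier of strategy (or condition) from
the mean orientation-period gaze altitude, validated both by repeated 25 %
hold-out (the reported p-value is the probability that fewer than half of
the held-out subjects are classified correctly) and by leave-one-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio

AGE_GROUPS = ("children", "young", "older")
CONDITIONS = ("landmark", "geometry")


@dataclass
class InteractionEstimate:
    delta: float                 # second difference, probability scale
    se: float
    p_value: float
    groups: tuple
    cell_probabilities: dict     # (age_group, condition) -> probability


@dataclass
class TestResult:
    name: str                    # 'U' | 'W' | 'F' | 'Fisher-p'
    statistic: float
    p_value: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    n: int | None = None
    odds_ratio: float | None = None
    odds_ratio_ci: tuple | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class ValidationReport:
    scheme: str                  # 'holdout25' | 'leave_one_out'
    overall_correct: float
    per_class_correct: dict
    distribution: np.ndarray | None = None   # hold-out repetition accuracies
    p_value: float | None = None
    n_subjects: int = 0
    n_reps: int | None = None


@dataclass
class StrategyFit:
    result: object               # statsmodels GLM results (ML or ridge)
    cell_probabilities: dict
    cell_counts: dict
    separation: bool


# ---------------------------------------------------------------------------
# interaction GLM

def fit_strategy_glm(cohort: pd.DataFrame) -> StrategyFit:
    """Binomial GLM of ``allocentric_majority`` on age group x condition.

    Requires every age x condition cell to be non-empty. Cell
    probabilities are reported as the observed proportions (the saturated
    maximum-likelihood values); the coefficient fit falls back to a small
    L2 ridge when a perfectly separated cell prevents ML convergence.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    cells = {}
    counts = {}
    for age in AGE_GROUPS:
        for cond in CONDITIONS:
            sub = cohort[(cohort.age_group == age) &
                         (cohort.condition == cond)]
            if len(sub) == 0:
                raise ValueError(f"empty design cell ({age}, {cond})")
            cells[(age, cond)] = float(sub.allocentric_majority.mean())
            counts[(age, cond)] = int(len(sub))

    model = smf.glm("allocentric_majority ~ C(age_group) * C(condition)",
                    data=cohort, family=sm.families.Binomial())
    separation = any(p in (0.0, 1.0) for p in cells.values())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if separation:
            result = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
        else:
            result = model.fit()
    return StrategyFit(result, cells, counts, separation)


def second_difference(fit: StrategyFit,
                      groups=("children", "young")) -> InteractionEstimate:
    """Probability-scale second difference between two age groups.

    ``groups = (g1, g2)`` yields the condition effect of g1 minus that of
    g2. The standard error is the delta-method value under the saturated
    fit (sum of binomial cell variances); the p-value is two-sided normal.
    """
    g1, g2 = groups
    for g in groups:
        if g not in AGE_GROUPS:
            raise ValueError(f"unknown age group {g!r}")
    p = fit.cell_probabilities
    n = fit.cell_counts
    delta = ((p[(g1, "geometry")] - p[(g1, "landmark")])
             - (p[(g2, "geometry")] - p[(g2, "landmark")]))
    var = sum(p[c] * (1 - p[c]) / n[c]
              for c in ((g1, "geometry"), (g1, "landmark"),
                        (g2, "geometry"), (g2, "landmark")))
    se = float(np.sqrt(var))
    z = delta / se if se > 0 else np.inf * np.sign(delta or 1)
    pval = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return InteractionEstimate(float(delta), se, pval, tuple(groups), dict(p))


def bootstrap_second_difference(cohort: pd.DataFrame, groups, reps: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Nonparametric bootstrap distribution of the second difference,
    resampling subjects within each design cell."""
    out = np.empty(reps)
    grouped = {k: v.allocentric_majority.to_numpy()
               for k, v in cohort.groupby(["age_group", "condition"])}
    g1, g2 = groups
    for r in range(reps):
        p = {}
        for cell, vals in grouped.items():
            p[cell] = rng.choice(vals, size=len(vals), replace=True).mean()
        out[r] = ((p[(g1, "geometry")] - p[(g1, "landmark")])
                  - (p[(g2, "geometry")] - p[(g2, "landmark")]))
    return out


# ---------------------------------------------------------------------------
# contingency tests

def fisher_2x2(table, alternative: str = "two-sided",
               ci_level: float = 0.95) -> TestResult:
    """Fisher's exact test with conditional-MLE odds ratio and effect sizes.

    For one-sided alternatives the odds-ratio confidence interval is the
    matching one-sided interval ``[L, inf)`` (or ``(0, U]``). phi is the
    Pearson correlation of the two binary margins; Cohen's w = |phi| for a
    2x2 table. The direction of a one-sided test is the caller's stated
    alternative, never inferred from the data.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("table has an all-zero margin")
    t = t.astype(int)
    _, p = sps.fisher_exact(t, alternative=alternative)
    res = _odds_ratio(t, kind="conditional")
    if alternative == "two-sided":
        ci = res.confidence_interval(confidence_level=ci_level)
        ci_t = (float(ci.low), float(ci.high))
    elif alternative == "greater":
        ci = res.confidence_interval(confidence_level=ci_level,
                                     alternative="greater")
        ci_t = (float(ci.low), np.inf)
    else:
        ci = res.confidence_interval(confidence_level=ci_level,
                                     alternative="less")
        ci_t = (0.0, float(ci.high))
    a, b = t[0]
    c, d = t[1]
    n = int(t.sum())
    denom = np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    phi = float((a * d - b * c) / denom) if denom > 0 else 0.0
    return TestResult("Fisher-p", float(p), float(p), phi, "phi", n,
                      odds_ratio=float(res.statistic), odds_ratio_ci=ci_t,
                      extra={"cohens_w": abs(phi)})


def cohens_w(table) -> float:
    """Cohen's w effect size of an r x c contingency table."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    chi2 = ((t - exp) ** 2 / exp).sum()
    return float(np.sqrt(chi2 / n))


def chisq_power_n(w: float, df: int, alpha: float = 0.05,
                  power: float = 0.8) -> int:
    """Minimal N for a chi-square test of effect size w to reach the
    target power: the smallest integer N whose noncentral chi-square power
    at noncentrality N * w**2 meets the target."""
    if w <= 0 or not 0 < alpha < 1 or not 0 < power < 1 or df < 1:
        raise ValueError("require w > 0, df >= 1, alpha and power in (0, 1)")
    crit = sps.chi2.ppf(1 - alpha, df)

    def achieved(n):
        return sps.ncx2.sf(crit, df, n * w * w)

    from scipy.optimize import brentq
    lam = brentq(lambda l: sps.ncx2.sf(crit, df, l) - power, 1e-9, 1e4)
    n = int(np.ceil(lam / (w * w) - 1e-9))
    while achieved(n) < power:
        n += 1
    while n > 1 and achieved(n - 1) >= power:
        n -= 1
    return n


# ---------------------------------------------------------------------------
# rank tests and factorial analysis

def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U with the study's effect size r = z / sqrt(N).

    z comes from the tie-corrected normal approximation of U (no
    continuity correction); the p-value is scipy's (exact for small
    tie-free samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("insufficient sample")
    res = sps.mannwhitneyu(x, y, alternative=alternative)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    ranks = sps.rankdata(np.concatenate([x, y]))
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie))
    z = (res.statistic - mu) / sigma if sigma > 0 else 0.0
    r = z / np.sqrt(n)
    return TestResult("U", float(res.statistic), float(res.pvalue),
                      float(r), "r", n, extra={"z": float(z)})


def wilcoxon_signed(diff, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test of paired differences against zero."""
    d = np.asarray(diff, dtype=float)
    if len(d) < 1:
        raise ValueError("insufficient sample")
    if np.all(d == 0):
        return TestResult("W", 0.0, 1.0, 0.0, "r", len(d),
                          extra={"degenerate": True})
    res = sps.wilcoxon(d, alternative=alternative)
    dd = d[d != 0]
    nz = len(dd)
    ranks = sps.rankdata(np.abs(dd))
    w_plus = float(ranks[dd > 0].sum())
    mu = nz * (nz + 1) / 4.0
    sigma = np.sqrt(nz * (nz + 1) * (2 * nz + 1) / 24.0)
    z = (w_plus - mu) / sigma if sigma > 0 else 0.0
    return TestResult("W", float(res.statistic), float(res.pvalue),
                      float(z / np.sqrt(len(d))), "r", len(d),
                      extra={"z": float(z)})


def anova_two_way(df: pd.DataFrame, response: str,
                  factors=("age_group", "condition"),
                  simple_effects: str | None = None) -> dict:
    """Two-way ANOVA with interaction; optional Bonferroni simple effects.

    Returns a dict of TestResult keyed by term. When ``simple_effects``
    names one factor, the effect of the *other* factor is tested within
    each of its levels and the p-values are Bonferroni-multiplied by the
    number of levels.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    fa, fb = factors
    data = df.dropna(subset=[response]).copy()
    if len(data) < 4:
        raise ValueError("insufficient sample")
    model = ols(f"{response} ~ C({fa}) * C({fb})", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {}
    names = {f"C({fa})": fa, f"C({fb})": fb,
             f"C({fa}):C({fb})": f"{fa}:{fb}"}
    for row, label in names.items():
        out[label] = TestResult("F", float(table.loc[row, "F"]),
                                float(table.loc[row, "PR(>F)"]),
                                n=int(len(data)),
                                extra={"df": float(table.loc[row, "df"])})
    if simple_effects is not None:
        within = simple_effects
        other = fb if within == fa else fa
        levels = sorted(data[within].unique())
        k = len(levels)
        for lev in levels:
            sub = data[data[within] == lev]
            m = ols(f"{response} ~ C({other})", data=sub).fit()
            t2 = sm.stats.anova_lm(m, typ=2)
            p_raw = float(t2.loc[f"C({other})", "PR(>F)"])
            out[f"simple:{other}@{within}={lev}"] = TestResult(
                "F", float(t2.loc[f"C({other})", "F"]),
                min(1.0, p_raw * k), n=int(len(sub)),
                extra={"p_uncorrected": p_raw, "bonferroni_m": k})
    return out


def compare_distributions(x, y=None, test: str = "mann_whitney",
                          **kw):
    """Dispatch to the study's distribution comparisons by name."""
    if test == "mann_whitney":
        return mann_whitney(x, y, **kw)
    if test == "wilcoxon":
        d = x if y is None else np.asarray(x) - np.asarray(y)
        return wilcoxon_signed(d, **kw)
    if test == "anova2":
        return anova_two_way(x, **kw)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# predictive model

def train_altitude_classifier(features, labels):
    """Single-predictor logistic classifier (decision threshold 0.5).

    A light L2 penalty keeps the fit defined under perfect separation
    while leaving the decision boundary effectively at the maximum-
    likelihood midpoint.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(features, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes to train the classifier")
    clf = LogisticRegression(C=1e4, max_iter=2000)
    clf.fit(X, y)
    return clf


def _per_class(y_true, y_pred) -> dict:
    out = {}
    for cls in np.unique(y_true):
        sel = y_true == cls
        out[cls] = float((y_pred[sel] == cls).mean())
    return out


def holdout_validate(features, labels, fraction: float = 0.25,
                     reps: int = 1000, seed: int | np.random.Generator = 0,
                     stratified: bool = True) -> ValidationReport:
    """Repeated hold-out validation of the altitude classifier.

    Each repetition trains on ``1 - fraction`` of the subjects and tests
    on the rest (stratified by class by default). The reported p-value is
    the fraction of repetitions in which fewer than half of the held-out
    subjects were correctly classified. Splits that leave a class absent
    from the training set are re-drawn.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    X = np.asarray(features, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 subjects to split")
    n_test = max(1, int(round(fraction * n)))
    accs = np.empty(reps)
    class_acc = {c: [] for c in classes}
    from sklearn.linear_model import LogisticRegression
    for r in range(reps):
        for _ in range(100):
            if stratified:
                test_idx = []
                for c in classes:
                    idx = np.nonzero(y == c)[0]
                    k = max(1, int(round(fraction * len(idx))))
                    test_idx.append(rng.choice(idx, size=k, replace=False))
                test_idx = np.concatenate(test_idx)
            else:
                test_idx = rng.choice(n, size=n_test, replace=False)
            train = np.setdiff1d(np.arange(n), test_idx)
            if len(np.unique(y[train])) == 2:
                break
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test_idx])
        accs[r] = float((pred == y[test_idx]).mean())
        for c, v in _per_class(y[test_idx], pred).items():
            class_acc[c].append(v)
    return ValidationReport(
        scheme="holdout25",
        overall_correct=float(accs.mean()),
        per_class_correct={c: float(np.mean(v)) for c, v in class_acc.items()},
        distribution=accs,
        p_value=float((accs < 0.5).mean()),
        n_subjects=n, n_reps=reps)


def loo_validate(features, labels) -> ValidationReport:
    """Leave-one-out validation: proportion of held-out subjects whose
    strategy (or condition) the classifier predicts correctly."""
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(features, dtype=float).reshape(-1, 1)
    y = np.asarray(labels, dtype=object)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    correct = np.zeros(n, dtype=bool)
    flagged = 0
    for i in range(n):
        train = np.delete(np.arange(n), i)
        if len(np.unique(y[train])) < 2:
            flagged += 1
            continue
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(X[train], y[train])
        correct[i] = clf.predict(X[i][None]) == y[i]
    return ValidationReport(
        scheme="leave_one_out",
        overall_correct=float(correct.mean()),
        per_class_correct=_per_class(y, np.where(
            correct, y, np.array(["__wrong__"] * n, dtype=object))),
        n_subjects=n,
        p_value=None,
        n_reps=None if flagged == 0 else flagged)
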