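"""Assumption-gated cohort statistics.

Mirrors the decision logic of classic biomedical statistics packages: every
group comparison is gated by Shapiro–Wilk normality tests (one per group) and
the Brown–Forsythe equal-variance test (Levene's test centred on the median).
If all gates pass at the gate alpha, the parametric test runs (t-test,
one-way ANOVA with Holm–Šidák pairwise post-hocs, two-way ANOVA); if any gate
fails, the rank-based analogue runs (Mann–Whitney, Kruskal–Wallis with Dunn's
post-hocs).  Post-hoc comparisons run only after a significant omnibus test.
All p-values are two-tailed; significance is p < 0.05.

Every result carries the gate evidence that routed it, so the decision is a
pure, auditable function of the data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, UndefinedCorrelationError

GATE_ALPHA = 0.05
SIG_ALPHA = 0.05


@dataclass
class GateEvidence:
    """Assumption-test p-values that routed a comparison."""

    normality_p: tuple[float, ...]
    variance_p: float
    passed: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class PostHoc:
    pair: tuple
    statistic: float
    p_adjusted: float


@dataclass
class StatResult:
    test_used: str
    statistic: float
    p_value: float
    gate: GateEvidence | None = None
    post_hoc: list[PostHoc] = field(default_factory=list)
    effects: dict = field(default_factory=dict)  # for two-way ANOVA

    @property
    def significant(self) -> bool:
        return self.p_value < SIG_ALPHA


def significance_marker(p: float, symbol: str = "*") -> str:
    """Figure-style marker: one/two/three symbols at 0.05/0.01/0.001."""
    for k, cut in ((3, 0.001), (2, 0.01), (1, 0.05)):
        if p < cut:
            return symbol * k
    return "ns"


def _shapiro_p(values: np.ndarray, notes: list[str]) -> float:
    if np.ptp(values) == 0:
        notes.append("zero-variance group: normality gate failed by convention")
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = sps.shapiro(values).pvalue
    return float(p) if np.isfinite(p) else 0.0


def check_gate(*groups: np.ndarray, alpha: float = GATE_ALPHA) -> GateEvidence:
    """Shapiro–Wilk per group plus Brown–Forsythe across groups."""
    notes: list[str] = []
    norm_p = tuple(_shapiro_p(np.asarray(g, dtype=float), notes) for g in groups)
    if any(np.ptp(g) == 0 for g in groups):
        var_p = 0.0
    else:
        var_p = float(sps.levene(*groups, center="median").pvalue)
    passed = all(p > alpha for p in norm_p) and var_p > alpha
    return GateEvidence(normality_p=norm_p, variance_p=var_p,
                       passed=passed, notes=notes)


def _as_groups(groups, min_n: int):
    out = [np.asarray(g, dtype=float) for g in groups]
    for g in out:
        if g.size < min_n:
            raise InsufficientDataError(f"need n >= {min_n} per group, got {g.size}")
        if np.any(~np.isfinite(g)):
            raise InsufficientDataError("missing/non-finite values inside a test")
    return out


def two_group_compare(a, b, alpha_gate: float = GATE_ALPHA) -> StatResult:
    """Gated two-group comparison: t-test or Mann–Whitney rank-sum.

    Both groups normal (Shapiro–Wilk) and homoscedastic (Brown–Forsythe) at
    ``alpha_gate`` routes to the two-sided t-test, anything else to the
    two-sided Mann–Whitney U test.
    """
    a, b = _as_groups((a, b), 3)
    gate = check_gate(a, b, alpha=alpha_gate)
    if gate.passed:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        return StatResult("t-test", float(stat), float(p), gate)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return StatResult("rank-sum", float(stat), float(p), gate)


def _holm_sidak(pvals: list[float]) -> np.ndarray:
    if not pvals:
        return np.array([])
    return multipletests(pvals, method="holm-sidak")[1]


def dunn_posthoc(groups: list[np.ndarray], pairs: list[tuple[int, int]]) -> list[PostHoc]:
    """Dunn's rank-based multiple comparisons after Kruskal–Wallis.

    Pools all observations, ranks with mid-ranks for ties, and compares mean
    ranks with the normal approximation including the tie correction; the
    resulting two-sided p-values are Holm–Šidák adjusted.
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    splits = np.cumsum([g.size for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    zs, ps = [], []
    for i, j in pairs:
        se = math.sqrt(var_unit * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (group_ranks[i].mean() - group_ranks[j].mean()) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
    adj = _holm_sidak(ps)
    return [PostHoc(pair=pairs[k], statistic=float(zs[k]), p_adjusted=float(adj[k]))
            for k in range(len(pairs))]


def multi_group_compare(groups, labels=None, alpha_gate: float = GATE_ALPHA) -> StatResult:
    """Gated >= 3 group comparison: one-way ANOVA or Kruskal–Wallis.

    Parametric route: one-way ANOVA, then Holm–Šidák-adjusted pairwise
    pooled-variance t-tests.  Nonparametric route: Kruskal–Wallis, then
    Dunn's test.  Post-hocs run only when the omnibus p < 0.05.  Groups may
    be unbalanced.
    """
    groups = _as_groups(groups, 3)
    if len(groups) < 3:
        raise InsufficientDataError("need at least three groups")
    labels = list(labels) if labels is not None else list(range(len(groups)))
    gate = check_gate(*groups, alpha=alpha_gate)
    pairs = list(itertools.combinations(range(len(groups)), 2))

    if gate.passed:
        stat, p = sps.f_oneway(*groups)
        result = StatResult("anova", float(stat), float(p), gate)
        if p < SIG_ALPHA:
            raw = [sps.ttest_ind(groups[i], groups[j], equal_var=True)
                   for i, j in pairs]
            adj = _holm_sidak([r.pvalue for r in raw])
            result.post_hoc = [
                PostHoc(pair=(labels[i], labels[j]),
                        statistic=float(raw[k].statistic), p_adjusted=float(adj[k]))
                for k, (i, j) in enumerate(pairs)]
        return result

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.kruskal(*groups)
    result = StatResult("anova-on-ranks", float(stat), float(p), gate)
    if p < SIG_ALPHA:
        result.post_hoc = [
            PostHoc(pair=(labels[i], labels[j]), statistic=ph.statistic,
                    p_adjusted=ph.p_adjusted)
            for ph, (i, j) in zip(dunn_posthoc(groups, pairs), pairs)]
    return result


def correlate(x, y) -> StatResult:
    """Pearson product-moment correlation with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance variable")
    r = sps.pearsonr(x, y)
    return StatResult("pearson", float(r.statistic), float(r.pvalue))


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "group",
    factor_b: str = "position",
) -> StatResult:
    """Two-way ANOVA on the cell-mean model with type-II sums of squares.

    Tests the main effects of both factors and, when every cell holds at
    least two observations, their interaction (with a single observation per
    cell the interaction is not estimable and an additive model is fitted).
    When the ``factor_a`` main effect is significant, pairwise ``factor_a``
    comparisons are run within each ``factor_b`` level, Holm–Šidák adjusted
    within level.

    ``StatResult.statistic``/``p_value`` report the ``factor_a`` main effect;
    the full effect table is in ``StatResult.effects``.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = data[[value, factor_a, factor_b]].dropna().copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise InsufficientDataError(f"factor {f!r} needs >= 2 levels")
    cell_n = df.groupby([factor_a, factor_b], observed=True)[value].count()
    with_interaction = bool((cell_n >= 2).all())
    formula = (f"{value} ~ C({factor_a}) * C({factor_b})" if with_interaction
               else f"{value} ~ C({factor_a}) + C({factor_b})")
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=2)

    effects = {}
    for row, name in ((f"C({factor_a})", factor_a), (f"C({factor_b})", factor_b),
                      (f"C({factor_a}):C({factor_b})", "interaction")):
        if row in table.index:
            effects[name] = {"F": float(table.loc[row, "F"]),
                             "p": float(table.loc[row, "PR(>F)"])}
    result = StatResult(
        "two-way-anova", statistic=effects[factor_a]["F"],
        p_value=effects[factor_a]["p"], effects=effects)

    if result.p_value < SIG_ALPHA:
        for level, sub in df.groupby(factor_b, observed=True):
            cells = {g: s[value].to_numpy() for g, s in sub.groupby(factor_a, observed=True)}
            pairs = [p for p in itertools.combinations(sorted(cells), 2)
                     if cells[p[0]].size >= 2 and cells[p[1]].size >= 2]
            raw = [sps.ttest_ind(cells[a], cells[b], equal_var=True) for a, b in pairs]
            adj = _holm_sidak([r.pvalue for r in raw])
            result.post_hoc += [
                PostHoc(pair=(a, b, level), statistic=float(raw[k].statistic),
                        p_adjusted=float(adj[k]))
                for k, (a, b) in enumerate(pairs)]
    return result
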