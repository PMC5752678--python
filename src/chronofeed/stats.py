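"""Group-statistics layer.

Two-sample t tests (from raw values or printed mean +/- SEM summaries),
balanced two-way repeated-measures (mixed-design) ANOVA, Holm-Sidak
step-down multiple comparisons, Pearson correlation, and the
normality/equal-variance screens (Shapiro-Wilk, Brown-Forsythe).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "CorrelationResult",
    "t_from_summary",
    "t_two_sample",
    "two_way_rm_anova",
    "holm_sidak",
    "pearson",
    "distribution_screens",
    "observed_power_t",
]


@dataclass(frozen=True)
class GroupSummary:
    """Group mean +/- SEM with sample size, as printed in results tables."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(label, float(v.mean()), float(sps.sem(v)), v.size)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    test_name: str


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def t_from_summary(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Two-sample t statistic from printed group summaries.

    t = (mean1 - mean2) / sqrt(sem1^2 + sem2^2) with df = n1 + n2 - 2 (the
    pooled convention; identical to the pooled raw-data t at equal n).
    Agreement with published statistics is limited to about 1% by the
    rounding of the printed means and SEMs.
    """
    denom = np.hypot(g1.sem, g2.sem)
    if denom == 0:
        if g1.mean == g2.mean:
            t = 0.0
        else:
            raise ZeroDivisionError(
                "both SEMs are zero with unequal means: t undefined"
            )
    else:
        t = (g1.mean - g2.mean) / denom
    df = g1.n + g2.n - 2
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), (float(df),), float(p), "t (from summary)")


def t_two_sample(x, y, mode: str = "pooled") -> TestResult:
    """Two-sample comparison on raw values.

    ``mode``: ``"pooled"`` (classical equal-variance t), ``"welch"``, or
    ``"ranksum"`` (two-sided Mann-Whitney U, the fallback used when
    normality fails).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    if mode == "ranksum":
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult(float(res.statistic), (np.nan,), float(res.pvalue), "Mann-Whitney U")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups: t degenerate")
    if mode == "pooled":
        res = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
        name = "t (pooled)"
    elif mode == "welch":
        res = sps.ttest_ind(x, y, equal_var=False)
        df = res.df
        name = "t (Welch)"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(float(res.statistic), (float(df),), float(res.pvalue), name)


def two_way_rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "animal",
    between: str = "treatment",
    within: str = "time",
) -> dict[str, TestResult]:
    """Balanced two-way mixed-design ANOVA (between treatment, within time).

    Every subject must be measured at every within level and each between
    group must hold the same number of subjects; missing cells raise rather
    than impute.  F ratios follow the standard partition for a mixed design:
    the between factor is tested against subjects-within-groups, the within
    factor and the interaction against the residual.  Degrees of freedom are
    reported as (df_between_groups, df_within_groups) pairs.  Sphericity is
    not corrected by default (apply Greenhouse-Geisser externally if
    required).
    """
    df = data[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise ValueError("missing responses: RM ANOVA requires complete cells")
    cell = df.groupby([subject, within], observed=True)[dv].count()
    n_subjects = df[subject].nunique()
    n_within = df[within].nunique()
    if len(cell) != n_subjects * n_within or (cell != 1).any():
        raise ValueError("design must have exactly one observation per subject x time cell")
    subjects = df.groupby(subject, observed=True)
    a_of_subj = subjects[between].first()
    a_levels = a_of_subj.unique()
    b_levels = df[within].unique()
    a, b = len(a_levels), len(b_levels)
    counts = a_of_subj.value_counts()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: equal subjects per group required")
    s = int(counts.iloc[0])

    grand = df[dv].mean()
    m_subj = subjects[dv].mean()
    m_a = df.groupby(between, observed=True)[dv].mean()
    m_b = df.groupby(within, observed=True)[dv].mean()
    m_ab = df.groupby([between, within], observed=True)[dv].mean()

    ss_a = b * s * float(((m_a - grand) ** 2).sum())
    ss_subj = b * float(((m_subj - m_a.reindex(a_of_subj).to_numpy()) ** 2).sum())
    ss_b = a * s * float(((m_b - grand) ** 2).sum())
    ss_ab = s * float(
        sum(
            (m_ab[(ai, bi)] - m_a[ai] - m_b[bi] + grand) ** 2
            for ai in a_levels
            for bi in b_levels
        )
    )
    ss_total = float(((df[dv] - grand) ** 2).sum())
    ss_err = ss_total - ss_a - ss_subj - ss_b - ss_ab

    df_a, df_subj = a - 1, a * (s - 1)
    df_b, df_ab = b - 1, (a - 1) * (b - 1)
    df_err = a * (s - 1) * (b - 1)

    def _f(ss_num, df_num, ss_den, df_den, name):
        if ss_den <= 0 or df_den <= 0:
            f = 0.0 if ss_num == 0 else np.inf
        else:
            ms_num, ms_den = ss_num / df_num, ss_den / df_den
            f = 0.0 if ms_den == 0 and ms_num == 0 else ms_num / ms_den
        p = float(sps.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
        return TestResult(float(f), (float(df_num), float(df_den)), p, name)

    return {
        between: _f(ss_a, df_a, ss_subj, df_subj, f"F ({between})"),
        within: _f(ss_b, df_b, ss_err, df_err, f"F ({within})"),
        "interaction": _f(ss_ab, df_ab, ss_err, df_err, "F (interaction)"),
    }


def holm_sidak(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down multiple-comparison adjustment.

    The i-th smallest p-value (1-based rank) is adjusted to
    ``1 - (1 - p)**(m - i + 1)``, with a running maximum enforcing
    monotonicity; step-down rejection stops at the first non-rejected
    hypothesis.  Returns ``(reject, p_adjusted)`` in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if adj_sorted[i] <= alpha:
            reject_sorted[i] = True
        else:
            break
    reject = np.empty(m, dtype=bool)
    reject[order] = reject_sorted
    return reject, adj


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def distribution_screens(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> dict[str, object]:
    """Normality and equal-variance screens applied before t tests.

    Shapiro-Wilk per group, and Brown-Forsythe (median-centred Levene)
    across groups.  Returns per-group Shapiro p-values, the Brown-Forsythe
    p, and boolean flags (True = assumption violated at ``alpha``).
    """
    shapiro_p = {}
    for label, v in groups.items():
        v = np.asarray(v, dtype=float)
        if v.size < 3:
            raise ValueError(f"group {label!r}: Shapiro-Wilk needs n >= 3")
        shapiro_p[label] = float(sps.shapiro(v).pvalue)
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        bf_p = float("nan")  # variance homogeneity needs two groups
    elif all(np.ptp(v) == 0 for v in arrays):
        bf_p = 1.0  # all groups constant: variances trivially equal
    else:
        bf_p = float(sps.levene(*arrays, center="median").pvalue)
    return {
        "shapiro_p": shapiro_p,
        "brown_forsythe_p": bf_p,
        "non_normal": {k: p < alpha for k, p in shapiro_p.items()},
        "unequal_variance": bool(bf_p < alpha),
    }


def observed_power_t(t_obs: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Post hoc power of a two-sample t test from its observed statistic.

    Standard noncentral-t computation with the observed t as the
    noncentrality parameter.  Note: this is a textbook quantity and is not
    numerically equivalent to the "observed power" column printed by some
    commercial statistics packages, whose formula is undocumented.
    """
    df = n1 + n2 - 2
    crit = sps.t.ppf(1 - alpha / 2, df)
    nc = abs(t_obs)
    return float(sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc))
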