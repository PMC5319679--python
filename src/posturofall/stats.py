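"""Normality-routed statistical comparisons.

The comparison workflow mirrors common practice in clinical posturography:
Shapiro-Wilk normality screening (alpha = 0.05) routes each comparison to a
parametric or rank-based test.

Paired condition comparisons (eyes open vs eyes closed): paired t-test when
the paired differences pass Shapiro-Wilk, Wilcoxon signed-rank otherwise.

Independent group comparisons (faller vs non-faller): Mann-Whitney U unless
both groups pass Shapiro-Wilk, in which case Levene's test routes to the
pooled-variance or Welch t-test.

Every result records the route taken so the convention is auditable.  Tests
are two-sided and no multiple-testing correction is applied (each variable
is tested at its own alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "paired_condition_compare",
    "independent_group_compare",
]

#: Largest sample size for which exact rank-test p-values are used
#: (ties force the normal approximation with tie correction).
EXACT_RANK_N = 25


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one routed comparison."""

    variable: str
    test: str
    statistic: float
    p_value: float
    normal: tuple[bool, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    ns: tuple[int, ...]

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    # Shapiro-Wilk is undefined for constant samples; a constant sample
    # carries no evidence against normality for routing purposes.
    if np.ptp(x) == 0:
        return True
    return sps.shapiro(x).pvalue >= alpha


def _rank_method(*samples: np.ndarray) -> str:
    pooled = np.concatenate(samples)
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties or max(len(s) for s in samples) > EXACT_RANK_N:
        return "approx"
    return "exact"


def paired_condition_compare(
    eo, ec, variable: str = "", alpha: float = 0.05
) -> ComparisonResult:
    """Compare paired eyes-open / eyes-closed samples.

    Shapiro-Wilk on the paired differences decides the route: paired t-test
    if the differences look normal, Wilcoxon signed-rank otherwise (exact
    p-value for n <= 25 without ties, normal approximation with tie and
    zero corrections otherwise).
    """
    eo = np.asarray(eo, dtype=float)
    ec = np.asarray(ec, dtype=float)
    if eo.shape != ec.shape or eo.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = eo.size
    if n < 3:
        raise ValueError("paired comparison requires n >= 3")
    diff = ec - eo
    normal = _shapiro_normal(diff, alpha)
    if normal:
        res = sps.ttest_rel(ec, eo)
        test, stat, p = "paired t", res.statistic, res.pvalue
        if np.isnan(stat):  # identical samples: zero effect, zero variance
            stat, p = 0.0, 1.0
    else:
        if np.all(diff == 0):
            test, stat, p = "wilcoxon", 0.0, 1.0
        else:
            method = _rank_method(diff[diff != 0])
            res = sps.wilcoxon(ec, eo, method=method, zero_method="wilcox")
            test, stat, p = "wilcoxon", res.statistic, res.pvalue
    return ComparisonResult(
        variable=variable,
        test=test,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        normal=(normal,),
        means=(float(eo.mean()), float(ec.mean())),
        sds=(float(eo.std(ddof=1)), float(ec.std(ddof=1))),
        ns=(n, n),
    )


def independent_group_compare(
    a, b, variable: str = "", alpha: float = 0.05
) -> ComparisonResult:
    """Compare two independent groups (e.g. non-fallers vs fallers).

    Both groups Shapiro-Wilk normal -> Levene's test (alpha) routes to the
    pooled-variance t-test (equal variances) or Welch's t-test (unequal);
    otherwise Mann-Whitney U (exact for n <= 25 without ties, normal
    approximation with tie correction otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("group samples must be 1-D arrays")
    if a.size < 3 or b.size < 3:
        raise ValueError("independent comparison requires n >= 3 per group")
    normal_a = _shapiro_normal(a, alpha)
    normal_b = _shapiro_normal(b, alpha)
    if normal_a and normal_b:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            equal_var = True
        else:
            equal_var = sps.levene(a, b).pvalue >= alpha
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test = "pooled t" if equal_var else "welch t"
        stat, p = res.statistic, res.pvalue
        if np.isnan(stat):
            stat, p = 0.0, 1.0
    else:
        method = _rank_method(a, b)
        res = sps.mannwhitneyu(
            a, b, method="exact" if method == "exact" else "asymptotic"
        )
        test, stat, p = "mann-whitney u", res.statistic, res.pvalue
    return ComparisonResult(
        variable=variable,
        test=test,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        normal=(normal_a, normal_b),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        ns=(a.size, b.size),
    )
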