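"""Statistical battery applied to navigational metrics.

Two-tailed exact binomial and Fisher tests for binary choice data, one- and
two-sample t-tests for continuous metrics, one-way ANOVA with Dunnett
many-to-one comparisons, and Benjamini–Hochberg adjustment for multiple
testing.  Every test returns a :class:`TestResult`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsError",
    "DegenerateVarianceError",
    "TestResult",
    "exact_binomial",
    "fisher_exact_2x2",
    "one_sample_t",
    "two_sample_t",
    "anova_dunnett",
    "bh_adjust",
    "adjust_family",
]


class StatsError(ValueError):
    pass


class DegenerateVarianceError(StatsError):
    """Zero-variance sample; the t statistic is undefined."""


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: Optional[int] = None
    df: Optional[float] = None
    adjusted_p: Optional[float] = None
    comparison: str = ""
    seed: Optional[int] = None
    extra: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise StatsError("p_value must be in [0, 1]")


def exact_binomial(k: int, n: int, p0: float = 0.5, comparison: str = "") -> TestResult:
    """Two-tailed exact binomial test of ``k`` successes out of ``n`` vs ``p0``.

    Two-tailed p by the small-probability summation convention: the sum of
    P(X = j) over all outcomes no more probable than the observed one.
    """
    if not 0 <= k <= n:
        raise StatsError("need 0 <= k <= n")
    res = sps.binomtest(k, n, p0, alternative="two-sided")
    return TestResult("exact_binomial", statistic=float(k), p_value=float(res.pvalue),
                      n=n, comparison=comparison, extra={"p0": p0})


def fisher_exact_2x2(table, comparison: str = "") -> TestResult:
    """Two-tailed Fisher's exact test on a 2×2 contingency table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise StatsError("table must be a non-negative 2x2 array")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult("fisher_exact", statistic=float(odds), p_value=float(p),
                      n=int(table.sum()), comparison=comparison)


def one_sample_t(values: Sequence[float], mu0: float = 0.0,
                 comparison: str = "") -> TestResult:
    """Two-tailed one-sample t-test of the mean of ``values`` against ``mu0``."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise StatsError("need at least 2 finite values")
    if np.ptp(x) == 0.0:
        raise DegenerateVarianceError("all values identical; t undefined")
    t, p = sps.ttest_1samp(x, mu0)
    return TestResult("one_sample_t", statistic=float(t), p_value=float(p),
                      n=len(x), df=len(x) - 1, comparison=comparison,
                      extra={"mu0": mu0})


def two_sample_t(a: Sequence[float], b: Sequence[float], equal_var: bool = True,
                 comparison: str = "") -> TestResult:
    """Two-tailed two-sample t-test (pooled variance by default)."""
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
    if len(xa) < 2 or len(xb) < 2:
        raise StatsError("need at least 2 finite values per sample")
    if np.ptp(np.concatenate([xa, xb])) == 0.0:
        raise DegenerateVarianceError("both samples constant; t undefined")
    t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
    df = (len(xa) + len(xb) - 2) if equal_var else None
    return TestResult("two_sample_t", statistic=float(t), p_value=float(p),
                      n=len(xa) + len(xb), df=df, comparison=comparison)


def anova_dunnett(groups: Dict[str, Sequence[float]], control: str,
                  seed: Optional[int] = None) -> List[TestResult]:
    """One-way ANOVA followed by Dunnett many-to-one comparisons.

    Returns the ANOVA F-test first, then one adjusted comparison per
    non-control group.  The family-wise adjustment integrates the
    multivariate-t distribution of the contrast statistics; ``seed`` fixes
    the quasi-random integration rule.
    """
    if control not in groups:
        raise StatsError(f"control group {control!r} not in groups")
    names = [g for g in groups if g != control]
    if not names:
        raise StatsError("need at least one non-control group")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise StatsError(f"group {g!r} needs >= 2 values")
    f, p_anova = sps.f_oneway(*arrays.values())
    k = len(arrays)
    n_total = sum(len(v) for v in arrays.values())
    results = [TestResult("anova_oneway", statistic=float(f), p_value=float(p_anova),
                          n=n_total, df=k - 1, comparison="between-groups",
                          extra={"df_within": n_total - k})]
    rng = np.random.default_rng(seed)
    dres = sps.dunnett(*[arrays[g] for g in names], control=arrays[control],
                       alternative="two-sided", rng=rng)
    for i, g in enumerate(names):
        results.append(TestResult(
            "dunnett", statistic=float(dres.statistic[i]),
            p_value=float(dres.pvalue[i]), n=len(arrays[g]) + len(arrays[control]),
            comparison=f"{g} vs {control}", seed=seed))
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns adjusted p-values in the input order: p_(i) * m / i with
    enforced monotonicity from the largest p downward, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def adjust_family(results: List[TestResult]) -> List[TestResult]:
    """Apply BH adjustment across a declared family of test results (in place)."""
    if not results:
        return results
    adj = bh_adjust([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    return results
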