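"""Cohort statistics: normality screening, one-way ANOVA with Tukey HSD
post-hoc, Pearson correlation and the Bonferroni correction.

These are the standard tests of the longitudinal analysis stage, wrapped as
thin validated operations over scipy.stats.  The normality screen is a
Lilliefors-style one-sample Kolmogorov-Smirnov test against a normal with
the sample's own mean and SD; because the parameters are estimated, the
p-value comes from a fixed-seed Monte-Carlo null rather than the classical
KS distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "PairwiseComparison",
    "ks_normality",
    "anova_oneway",
    "tukey_hsd",
    "pearson_corr",
    "bonferroni_adjust",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    p_adjusted: float


def _lilliefors_stat(values: np.ndarray) -> float:
    mu = values.mean()
    sd = values.std(ddof=1)
    return float(sps.kstest(values, "norm", args=(mu, sd)).statistic)


def ks_normality(values: Sequence[float], n_sim: int = 2000, seed: int = 0) -> tuple[float, float]:
    """One-sample KS normality statistic with estimated mean/SD.

    Returns ``(statistic, p)``; the p-value is Monte-Carlo calibrated
    (``n_sim`` standard-normal samples of the same size, fixed ``seed``),
    which corrects the classical KS null for the estimated parameters.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 5:
        raise ValueError(f"normality test needs at least 5 values, got {values.size}")
    if values.std(ddof=1) == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    stat = _lilliefors_stat(values)
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_sim, values.size))
    null = np.array([_lilliefors_stat(s) for s in sims])
    p = (1 + int((null >= stat).sum())) / (n_sim + 1)
    return stat, float(p)


def _validated_groups(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        names = [str(k) for k in groups]
        arrays = [np.asarray(v, dtype=np.float64) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=np.float64) for v in groups]
        names = [str(i) for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate data: all values identical")
    return names, arrays


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    ``groups`` is a mapping label -> values or a sequence of value arrays.
    """
    _, arrays = _validated_groups(groups)
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def tukey_hsd(groups) -> list[PairwiseComparison]:
    """Tukey honestly-significant-difference post-hoc comparisons with
    studentized-range adjusted p-values, one entry per group pair."""
    names, arrays = _validated_groups(groups)
    res = sps.tukey_hsd(*arrays)
    out = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            out.append(
                PairwiseComparison(
                    group_a=names[i],
                    group_b=names[j],
                    mean_diff=float(arrays[i].mean() - arrays[j].mean()),
                    p_adjusted=float(res.pvalue[i, j]),
                )
            )
    return out


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Per-test significance level alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError(f"number of comparisons must be a positive integer, got {m}")
    return alpha / m
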