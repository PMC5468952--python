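"""Normality-gated group comparisons and mean +/- SEM summaries.

The decision procedure used for every group comparison in the pipeline:

* each sample is tested for normality with a one-sample Kolmogorov-Smirnov
  test against a normal distribution with the sample's own mean and SD;
* if both samples pass (p > 0.05), a two-tailed Student's t-test is used
  (the paired variant for longitudinal data);
* otherwise the nonparametric counterpart is used — Mann-Whitney for
  independent samples, Wilcoxon signed-rank for paired samples;
* significance is declared at p <= 0.05 (inclusive).

Plain KS with estimated parameters is the default gate; the Lilliefors
correction (which accounts for the estimation and is less conservative) is
available via ``method="lilliefors"``.  Data are summarized as
mean +/- SEM with SEM = SD / sqrt(n) (sample SD, n-1 denominator).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import stats

__all__ = ["Summary", "GroupComparison", "normality_gate", "compare", "summarize"]

ALPHA = 0.05
MIN_GATE_N = 8

_TEST_T = "Student t (two-tailed)"
_TEST_MW = "Mann-Whitney"
_TEST_WSR = "Wilcoxon signed-rank"


@dataclasses.dataclass(frozen=True)
class Summary:
    """Mean +/- SEM of one sample."""

    mean: float
    sem: float | None
    n: int

    @property
    def text(self) -> str:
        if self.sem is None:
            return f"{self.mean:.1f} ± n/a"
        return f"{self.mean:.1f} ± {self.sem:.1f}"


def summarize(sample) -> Summary:
    """Mean and standard error (SD / sqrt(n), sample SD) of a sample."""
    x = np.asarray(sample, dtype=float)
    if x.size < 1:
        raise ValueError("summarize needs at least one value")
    sem = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else None
    return Summary(mean=float(x.mean()), sem=sem, n=int(x.size))


def normality_gate(
    sample, *, alpha: float = ALPHA, min_n: int = MIN_GATE_N, method: str = "ks"
) -> bool:
    """True when the sample is consistent with a normal distribution.

    A one-sample KS test against N(sample mean, sample SD) must yield
    p > ``alpha``.  Samples smaller than ``min_n`` (or with zero variance)
    fail the gate — with a warning for the former — which routes the
    comparison to the nonparametric test.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < min_n:
        warnings.warn(
            f"sample of n={x.size} is too small for a normality test; "
            "falling back to the nonparametric comparison",
            stacklevel=2,
        )
        return False
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return False
    if method == "ks":
        p = float(stats.kstest(x, "norm", args=(float(x.mean()), sd)).pvalue)
    elif method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        _, p = lilliefors(x, dist="norm")
        p = float(p)
    else:
        raise ValueError(f"unknown normality test method {method!r}")
    return p > alpha


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Outcome of one gated group comparison."""

    test_name: str
    paired: bool
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    significant: bool
    mean_sem_a: Summary
    mean_sem_b: Summary
    gate_a: bool
    gate_b: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.paired and self.n_a != self.n_b:
            raise ValueError("paired comparison requires equal sample sizes")
        expected = _expected_test(self.gate_a and self.gate_b, self.paired)
        if self.test_name != expected:
            raise ValueError(
                f"test {self.test_name!r} inconsistent with gate outcome "
                f"(expected {expected!r})"
            )


def _expected_test(both_normal: bool, paired: bool) -> str:
    if both_normal:
        return _TEST_T
    return _TEST_WSR if paired else _TEST_MW


def compare(
    sample_a,
    sample_b,
    paired: bool = False,
    *,
    alpha: float = ALPHA,
    method: str = "ks",
) -> GroupComparison:
    """Gated two-group comparison.

    Both samples pass the normality gate -> two-tailed Student's t-test
    (paired variant when ``paired``); otherwise Mann-Whitney (independent)
    or Wilcoxon signed-rank (paired).  Identical paired samples are a
    degenerate no-difference case reported with p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if paired and a.size != b.size:
        raise ValueError("paired samples must have equal lengths")
    gate_a = normality_gate(a, alpha=alpha, method=method)
    gate_b = normality_gate(b, alpha=alpha, method=method)
    both = gate_a and gate_b

    degenerate_pair = paired and bool(np.all(a == b))
    if both:
        name = _TEST_T
        if degenerate_pair:
            stat, p = 0.0, 1.0
        elif paired:
            stat, p = stats.ttest_rel(a, b)
        else:
            stat, p = stats.ttest_ind(a, b)
    elif paired:
        name = _TEST_WSR
        if degenerate_pair:
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(a, b)
            stat, p = res.statistic, res.pvalue
    else:
        name = _TEST_MW
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = res.statistic, res.pvalue

    p = float(p)
    return GroupComparison(
        test_name=name,
        paired=paired,
        n_a=int(a.size),
        n_b=int(b.size),
        statistic=float(stat),
        p_value=p,
        significant=p <= alpha,
        mean_sem_a=summarize(a),
        mean_sem_b=summarize(b),
        gate_a=gate_a,
        gate_b=gate_b,
    )
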