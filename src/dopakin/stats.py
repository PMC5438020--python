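"""Descriptive and inferential statistics on Ki_cer tables.

Implements the challenge-study battery: the percentage-change convention
(baseline − post)/baseline × 100 (negative when the post-challenge value is
*higher*), Pearson/Spearman correlations with caller-specified exclusions,
paired and summary-statistics t-tests, test–retest reliability (ICC and
test–retest variability) and a Lilliefors-corrected Kolmogorov–Smirnov
normality check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .errors import DegenerateInputError, DomainError, InsufficientDataError

__all__ = [
    "CorrelationResult",
    "TTestResult",
    "ReliabilityResult",
    "percent_change",
    "correlate",
    "paired_t",
    "two_sample_t_summary",
    "reliability",
    "ks_normality",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_two_tailed: float
    method: str
    excluded_ids: tuple = ()

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "n": self.n,
            "p_two_tailed": self.p_two_tailed,
            "method": self.method,
            "excluded_ids": list(self.excluded_ids),
        }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_tailed: float
    kind: str

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p_two_tailed": self.p_two_tailed, "kind": self.kind}


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    icc_variant: str
    trv_percent: float
    n: int

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "icc_variant": self.icc_variant,
            "trv_percent": self.trv_percent,
            "n": self.n,
        }


def percent_change(ki_baseline, ki_post):
    """Percentage change (baseline − post)/baseline × 100.

    Positive when the post value decreased, negative when it increased —
    the convention under which a mean post-challenge *increase* prints as a
    negative mean percentage change. Accepts scalars or arrays; the
    baseline must be strictly positive.
    """
    b = np.asarray(ki_baseline, dtype=float)
    p = np.asarray(ki_post, dtype=float)
    if np.any(b <= 0):
        raise DomainError("baseline Ki must be positive")
    out = (b - p) / b * 100.0
    return out if out.ndim else float(out)


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    ids: Sequence | None = None,
    excluded_ids: Sequence = (),
) -> CorrelationResult:
    """Pearson or Spearman correlation with explicit, audited exclusions.

    Exclusions are by identifier only (never automatic): ``ids`` aligns an
    identifier with each observation and entries of ``excluded_ids`` are
    dropped from both vectors before the correlation.
    """
    if method not in ("pearson", "spearman"):
        raise DomainError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d and of equal length")
    excluded = tuple(excluded_ids)
    if excluded:
        if ids is None:
            raise DomainError("excluded_ids given without ids")
        keep = ~np.isin(np.asarray(ids), list(excluded))
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    else:
        res = sps.spearmanr(x, y)
    return CorrelationResult(
        r=float(res.statistic),
        n=int(x.size),
        p_two_tailed=float(res.pvalue),
        method=method,
        excluded_ids=excluded,
    )


def paired_t(pre: Sequence[float], post: Sequence[float]) -> TTestResult:
    """Paired t-test on pre/post vectors (df = n − 1, two-tailed)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise InsufficientDataError("need paired vectors of equal length >= 2")
    d = pre - post
    if np.ptp(d) == 0:
        if np.all(d == 0):
            return TTestResult(t=0.0, df=float(pre.size - 1), p_two_tailed=1.0, kind="paired")
        raise DegenerateInputError("constant nonzero difference: zero variance")
    t, p = sps.ttest_rel(pre, post)
    return TTestResult(t=float(t), df=float(pre.size - 1), p_two_tailed=float(p), kind="paired")


def two_sample_t_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, equal_var: bool = True
) -> TTestResult:
    """Two-sample t-test from summary statistics (means, SDs, ns).

    Pooled-variance by default (df = n1 + n2 − 2, matching a printed
    t₁₄ for two groups of 8); ``equal_var=False`` gives Welch's test.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need n >= 2 in each group")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise DegenerateInputError("SDs must be >= 0 and not both zero")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:  # Welch–Satterthwaite
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(
        t=float(res.statistic), df=df, p_two_tailed=float(res.pvalue), kind="two_sample_summary"
    )


def reliability(
    scan1: Sequence[float], scan2: Sequence[float], icc_variant: str = "agreement"
) -> ReliabilityResult:
    """Test–retest reliability: ICC and test–retest variability.

    ``icc_variant='agreement'`` is ICC(A,1), the two-way absolute-agreement
    single-measure coefficient; ``'consistency'`` is ICC(C,1). Test–retest
    variability (TRV) is the mean over subjects of
    |scan1 − scan2| / mean(scan1, scan2) × 100.
    """
    if icc_variant not in ("agreement", "consistency"):
        raise DomainError(f"unknown icc_variant {icc_variant!r}")
    s1 = np.asarray(scan1, dtype=float)
    s2 = np.asarray(scan2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1 or s1.size < 3:
        raise InsufficientDataError("need paired scans of equal length >= 3")
    if np.ptp(np.concatenate([s1, s2])) == 0:
        raise DegenerateInputError("zero total variance across scans")
    n = s1.size
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "scan": np.repeat(["scan1", "scan2"], n),
            "score": np.concatenate([s1, s2]),
        }
    )
    icc_table = pg.intraclass_corr(
        data=long, targets="subject", raters="scan", ratings="score"
    ).set_index("Type")
    icc = float(icc_table.loc["ICC(A,1)" if icc_variant == "agreement" else "ICC(C,1)", "ICC"])
    trv = float(np.mean(np.abs(s1 - s2) / ((s1 + s2) / 2.0)) * 100.0)
    return ReliabilityResult(icc=icc, icc_variant=icc_variant, trv_percent=trv, n=int(n))


def ks_normality(x: Sequence[float]) -> tuple[float, float]:
    """Kolmogorov–Smirnov normality test with estimated parameters.

    One-sample KS statistic against Normal(mean(x), sd(x)) with the
    Lilliefors small-sample correction of the p-value (the reference
    parameters are estimated from the data, so the classic KS null
    distribution would be anticonservative).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise InsufficientDataError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance sample")
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)
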