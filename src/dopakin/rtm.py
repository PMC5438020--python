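"""Regression-to-the-mean test battery and its calibration.

A negative correlation between baseline Ki_cer and its change on
re-scanning can arise from genuine regulation or from measurement error
alone (regression to the mean). The battery bundles the four classical
checks used to separate the two:

* Levene's test for equal change-score variance across arms,
* the group × change interaction of a two-arm, two-scan repeated-measures
  ANOVA (algebraically identical, for two groups and two scans, to the
  squared pooled two-sample t on change scores),
* a linear regression predicting the second scan from baseline, arm and
  their interaction (whose baseline×arm coefficient recovers −gamma of the
  set-point regulation model exactly on noise-free data),
* a Fisher r-to-z comparison of the per-arm baseline-vs-percent-change
  correlations.

``calibration_sim`` measures the battery's actual type-I error and power
against the generative cohort model by Monte-Carlo simulation of whole
study pairs at the study's arm sizes (8 test–retest, 12 challenge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .cohort import ARM_CHALLENGE, ARM_TEST_RETEST, CohortConfig, _draw_arm
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    DomainError,
    IncompleteDesignError,
    InsufficientDataError,
    SingularDesignError,
)
from .stats import CorrelationResult, correlate, percent_change

__all__ = [
    "AnovaResult",
    "RegressionFit",
    "CorrelationComparison",
    "RTMReport",
    "levene",
    "mixed_anova_interaction",
    "interaction_regression",
    "fisher_z",
    "compare_correlations",
    "rtm_battery",
    "calibration_sim",
]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float

    def to_dict(self) -> dict:
        return {"f": self.f, "df1": self.df1, "df2": self.df2, "p": self.p}


@dataclass(frozen=True)
class RegressionFit:
    """OLS of second-scan Ki on {1, baseline, arm, baseline×arm}."""

    coefficients: dict
    standard_errors: dict
    p_values: dict
    f: float
    f_p: float
    adjusted_r2: float
    n: int

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "p_values": self.p_values,
            "f": self.f,
            "f_p": self.f_p,
            "adjusted_r2": self.adjusted_r2,
            "n": self.n,
        }


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z1: float
    z2: float
    z_diff: float
    p_two_tailed: float
    method: str

    def to_dict(self) -> dict:
        return {
            "r1": self.r1, "n1": self.n1, "r2": self.r2, "n2": self.n2,
            "z1": self.z1, "z2": self.z2, "z_diff": self.z_diff,
            "p_two_tailed": self.p_two_tailed, "method": self.method,
        }


@dataclass(frozen=True)
class RTMReport:
    levene_w: float
    levene_p: float
    anova: AnovaResult
    regression: RegressionFit
    correlation_test_retest: CorrelationResult | None
    correlation_challenge: CorrelationResult | None
    correlation_comparison: CorrelationComparison | None
    degenerate: dict
    excluded_ids: tuple

    def to_dict(self) -> dict:
        return {
            "levene": {"w": self.levene_w, "p": self.levene_p},
            "anova": self.anova.to_dict(),
            "regression": self.regression.to_dict(),
            "correlation_test_retest": (
                None if self.correlation_test_retest is None else self.correlation_test_retest.to_dict()
            ),
            "correlation_challenge": (
                None if self.correlation_challenge is None else self.correlation_challenge.to_dict()
            ),
            "correlation_comparison": (
                None if self.correlation_comparison is None else self.correlation_comparison.to_dict()
            ),
            "degenerate": self.degenerate,
            "excluded_ids": list(self.excluded_ids),
            # percent change follows the (baseline − post)/baseline convention;
            # under the increase convention (post − baseline)/baseline every
            # baseline-vs-change correlation simply flips sign
            "sign_conventions": {
                "percent_change": "(baseline - post)/baseline * 100",
                "r_test_retest_increase_convention": (
                    None if self.correlation_test_retest is None else -self.correlation_test_retest.r
                ),
                "r_challenge_increase_convention": (
                    None if self.correlation_challenge is None else -self.correlation_challenge.r
                ),
            },
        }


def levene(groups: list, center: str = "mean") -> tuple[float, float]:
    """Levene's test of equal variances across groups.

    One-way ANOVA on absolute deviations from each group's ``center``
    (``mean`` for the classical test, ``median`` for the Brown–Forsythe
    variant). Returns (W, p).
    """
    if center not in ("mean", "median"):
        raise DomainError(f"center must be 'mean' or 'median', got {center!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InsufficientDataError("need at least two groups")
    for g in arrays:
        if g.size < 2:
            raise InsufficientDataError("every group needs n >= 2")
    # all deviations identically zero: no dispersion anywhere, W = 0 by convention
    if all(np.ptp(g) == 0 for g in arrays):
        return 0.0, 1.0
    w, p = sps.levene(*arrays, center=center)
    return float(w), float(p)


def _change_score_t(d1: np.ndarray, d2: np.ndarray) -> tuple[float, int]:
    """Pooled two-sample t on change scores; returns (t, df)."""
    n1, n2 = d1.size, d2.size
    v1 = d1.var(ddof=1)
    v2 = d2.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 == 0:
        return (0.0 if d1.mean() == d2.mean() else math.inf), n1 + n2 - 2
    t = (d1.mean() - d2.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, n1 + n2 - 2


def mixed_anova_interaction(cohort: pd.DataFrame) -> AnovaResult:
    """Group × change interaction F of the two-arm, two-scan design.

    For two groups and two scans the interaction F of the mixed
    repeated-measures ANOVA equals the squared pooled two-sample t on the
    change scores, with df = (1, N − 2); that identity is used directly
    (sphericity is trivially satisfied with two within-subject levels).
    """
    required = {"arm", "ki_scan1", "ki_scan2"}
    if not required.issubset(cohort.columns):
        raise IncompleteDesignError(f"cohort table needs columns {sorted(required)}")
    if cohort[["ki_scan1", "ki_scan2"]].isna().any().any():
        raise IncompleteDesignError("missing scan values")
    arms = cohort["arm"].unique()
    if len(arms) != 2:
        raise IncompleteDesignError(f"need exactly 2 arms, got {list(arms)}")
    d = (cohort["ki_scan2"] - cohort["ki_scan1"]).to_numpy()
    mask = (cohort["arm"] == arms[0]).to_numpy()
    d1, d2 = d[mask], d[~mask]
    if d1.size < 2 or d2.size < 2:
        raise IncompleteDesignError("need n >= 2 in each arm")
    t, df2 = _change_score_t(d1, d2)
    f = t * t
    p = 1.0 if not math.isfinite(f) else float(sps.f.sf(f, 1, df2))
    return AnovaResult(f=float(f), df1=1, df2=int(df2), p=(0.0 if not math.isfinite(f) else p))


def _interaction_f_cellmeans(cohort: pd.DataFrame) -> float:
    """Sums-of-squares route to the interaction F, kept for validation.

    Removes per-subject means (the between-subject stratum), then forms the
    group × scan interaction and within-cell error sums of squares in the
    within-subject stratum.
    """
    d = (cohort["ki_scan2"] - cohort["ki_scan1"]).to_numpy()
    arms = cohort["arm"].unique()
    groups = [d[(cohort["arm"] == a).to_numpy()] for a in arms]
    n = np.array([g.size for g in groups])
    grand = d.mean()
    # after subject-centring, scan deviations are ±d/2, so all within-subject
    # sums of squares carry a factor 1/2 that cancels in the F ratio
    ss_int = float(np.sum(n * (np.array([g.mean() for g in groups]) - grand) ** 2)) / 2.0
    ss_err = float(sum(np.sum((g - g.mean()) ** 2) for g in groups)) / 2.0
    df2 = int(n.sum() - len(groups))
    if ss_err == 0:
        return 0.0 if ss_int == 0 else math.inf
    return (ss_int / (len(groups) - 1)) / (ss_err / df2)


def interaction_regression(cohort: pd.DataFrame, challenge_label: str = ARM_CHALLENGE) -> RegressionFit:
    """OLS of ki_scan2 on {1, ki_scan1, arm, ki_scan1 × arm}.

    The arm indicator is 1 for the challenge arm. Under the set-point
    regulation model the baseline×arm coefficient equals −gamma, so the fit
    is also a parameter-recovery device. Reports the overall F and adjusted
    R² alongside per-coefficient inference.
    """
    if len(cohort) < 5:
        raise InsufficientDataError("need N >= 5 subjects")
    baseline = cohort["ki_scan1"].to_numpy(dtype=float)
    y = cohort["ki_scan2"].to_numpy(dtype=float)
    group = (cohort["arm"] == challenge_label).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(baseline), baseline, group, baseline * group])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient (single arm or constant baseline)")
    fit = sm.OLS(y, X).fit()
    names = ["intercept", "baseline", "group", "baseline_x_group"]
    return RegressionFit(
        coefficients=dict(zip(names, (float(v) for v in fit.params))),
        standard_errors=dict(zip(names, (float(v) for v in fit.bse))),
        p_values=dict(zip(names, (float(v) for v in fit.pvalues))),
        f=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        adjusted_r2=float(fit.rsquared_adj),
        n=int(len(cohort)),
    )


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing r-to-z transform, z = atanh(r)."""
    if not -1.0 < r < 1.0:
        raise DomainError("fisher_z requires |r| < 1")
    return float(np.arctanh(r))


def compare_correlations(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    method: str = "independent",
    r_cross: float | None = None,
) -> CorrelationComparison:
    """Compare two correlation coefficients after Fisher r-to-z.

    ``independent`` (default): the two correlations come from disjoint
    samples; z_diff = (z1 − z2)/sqrt(1/(n1−3) + 1/(n2−3)), two-tailed
    Normal p. ``steiger_dependent``: both correlations share a variable in
    one sample of size n1 (n2 is ignored); requires ``r_cross``, the
    correlation between the two non-shared variables, and uses Steiger's
    pooled-r Z1* statistic.
    """
    if not (-1.0 < r1 < 1.0 and -1.0 < r2 < 1.0):
        raise DomainError("correlations must satisfy |r| < 1")
    if n1 <= 3 or (method == "independent" and n2 <= 3):
        raise InsufficientDataError("need n >= 4 per correlation")
    z1, z2 = fisher_z(r1), fisher_z(r2)
    if method == "independent":
        se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        z_diff = (z1 - z2) / se
    elif method == "steiger_dependent":
        if r_cross is None:
            raise DomainError("steiger_dependent requires r_cross, the correlation "
                              "between the two non-shared variables")
        rbar = 0.5 * (r1 + r2)
        # Steiger (pooled-r) covariance of the two dependent correlations
        num = r_cross * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r_cross**2)
        s12 = num / (1.0 - rbar**2) ** 2
        z_diff = (z1 - z2) * math.sqrt((n1 - 3) / (2.0 - 2.0 * s12))
    else:
        raise DomainError(f"unknown method {method!r}")
    p = float(2.0 * sps.norm.sf(abs(z_diff)))
    return CorrelationComparison(
        r1=float(r1), n1=int(n1), r2=float(r2), n2=int(n2),
        z1=z1, z2=z2, z_diff=float(z_diff), p_two_tailed=p, method=method,
    )


def rtm_battery(
    test_retest: pd.DataFrame,
    challenge: pd.DataFrame,
    exclusions: tuple = (),
) -> RTMReport:
    """Run the full regression-to-the-mean battery on two cohort tables.

    ``exclusions`` lists subject_ids dropped (recorded in the report)
    before any analysis. Degenerate components (e.g. zero-variance percent
    changes on a noise-free null cohort) are flagged under ``degenerate``
    rather than raising.
    """
    excl = tuple(exclusions)

    def prep(df: pd.DataFrame, arm: str) -> pd.DataFrame:
        df = df.copy()
        if "arm" in df.columns:
            # allow a combined two-arm table on either side
            df = df[df["arm"] == arm]
        else:
            df["arm"] = arm
        if excl:
            df = df[~df["subject_id"].isin(excl)]
        if len(df) < 2:
            raise IncompleteDesignError(f"{arm} arm has fewer than 2 usable subjects")
        return df

    tr = prep(test_retest, ARM_TEST_RETEST)
    ch = prep(challenge, ARM_CHALLENGE)
    pooled = pd.concat([tr, ch], ignore_index=True)

    d_tr = (tr["ki_scan2"] - tr["ki_scan1"]).to_numpy()
    d_ch = (ch["ki_scan2"] - ch["ki_scan1"]).to_numpy()
    lev_w, lev_p = levene([d_tr, d_ch], center="mean")
    anova = mixed_anova_interaction(pooled)
    regression = interaction_regression(pooled)

    degenerate: dict = {}
    corr_tr = corr_ch = comparison = None
    try:
        corr_tr = correlate(
            tr["ki_scan1"], percent_change(tr["ki_scan1"], tr["ki_scan2"]), method="pearson"
        )
    except DegenerateInputError as e:
        degenerate["correlation_test_retest"] = str(e)
    try:
        corr_ch = correlate(
            ch["ki_scan1"], percent_change(ch["ki_scan1"], ch["ki_scan2"]), method="pearson"
        )
    except DegenerateInputError as e:
        degenerate["correlation_challenge"] = str(e)
    if corr_tr is not None and corr_ch is not None:
        try:
            comparison = compare_correlations(corr_tr.r, corr_tr.n, corr_ch.r, corr_ch.n)
        except DomainError as e:
            degenerate["correlation_comparison"] = str(e)

    return RTMReport(
        levene_w=lev_w,
        levene_p=lev_p,
        anova=anova,
        regression=regression,
        correlation_test_retest=corr_tr,
        correlation_challenge=corr_ch,
        correlation_comparison=comparison,
        degenerate=degenerate,
        excluded_ids=excl,
    )


def _fast_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt(float(xd @ xd) * float(yd @ yd))
    if denom == 0:
        return 0.0
    return float(xd @ yd) / denom


def calibration_sim(
    gammas,
    n_sim: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    base_config: CohortConfig | None = None,
    n_test_retest: int = 8,
    n_challenge: int = 12,
) -> pd.DataFrame:
    """Type-I error / power of the battery over a grid of regulation strengths.

    For each gamma, simulates ``n_sim`` complete study pairs at the study's
    arm sizes from the cohort generative model and records the fraction
    rejecting at ``alpha`` for (a) the ANOVA interaction and (b) the
    independent Fisher-z comparison of the per-arm baseline-vs-percent-change
    correlations. At gamma = 0 both rates estimate the false-positive rate
    under pure measurement noise.
    """
    if n_sim < 100:
        raise ConfigurationError("n_sim must be >= 100 for stable rejection rates")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    base = base_config if base_config is not None else CohortConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for gamma in gammas:
        cfg = replace(base, gamma=float(gamma))
        t_stats = np.empty(n_sim)
        z_diffs = np.empty(n_sim)
        for i in range(n_sim):
            _, tr1, tr2 = _draw_arm(rng, cfg, n_test_retest, challenge=False)
            _, ch1, ch2 = _draw_arm(rng, cfg, n_challenge, challenge=True)
            t_stats[i], _ = _change_score_t(tr2 - tr1, ch2 - ch1)
            r_tr = np.clip(_fast_pearson(tr1, (tr1 - tr2) / tr1), -0.999999, 0.999999)
            r_ch = np.clip(_fast_pearson(ch1, (ch1 - ch2) / ch1), -0.999999, 0.999999)
            se = math.sqrt(1.0 / (n_test_retest - 3) + 1.0 / (n_challenge - 3))
            z_diffs[i] = (math.atanh(r_tr) - math.atanh(r_ch)) / se
        df2 = n_test_retest + n_challenge - 2
        p_anova = 2.0 * sps.t.sf(np.abs(t_stats), df2)
        p_corr = 2.0 * sps.norm.sf(np.abs(z_diffs))
        rows.append(
            {
                "gamma": float(gamma),
                "anova_rejection_rate": float(np.mean(p_anova < alpha)),
                "correlation_rejection_rate": float(np.mean(p_corr < alpha)),
                "n_sim": int(n_sim),
                "alpha": float(alpha),
            }
        )
    return pd.DataFrame(rows)
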