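"""Statistical toolbox: two-sample tests, chi-square, Mann-Whitney,
BH-FDR, partial/Spearman correlation, and noncentral-t power analysis.

All two-sample t-tests are pooled-variance (df = n1 + n2 - 2), the
convention under which the cohort's reported degrees of freedom
(34 + 33 - 2 = 65) are consistent.  The chi-square test applies no
continuity correction.  Sample-size planning uses the exact noncentral-t
distribution function rather than a normal approximation: the two differ
at the margins that matter for small cohorts (the normal approximation
under-counts by one subject per group at d = 0.7, alpha = 0.05,
power = 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult", "PowerSpec", "CorrelationResult",
    "two_sample_t", "t_from_summary", "p_from_t", "chi_square_2x2",
    "fisher_exact_2x2", "mann_whitney", "bh_fdr", "partial_pearson",
    "spearman", "power_two_sample_t", "required_sample_size",
]


@dataclass
class GroupTestResult:
    """Outcome of one group-difference test on one connectivity/metric unit."""

    unit_label: str
    estimate: float
    t_stat: float
    df: int
    p: float
    p_fdr: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range for {self.unit_label}: {self.p}")


@dataclass
class PowerSpec:
    """Inputs to a two-sample t-test power / sample-size calculation."""

    effect_size_d: float
    alpha: float = 0.05
    power: float = 0.8
    allocation_ratio: float = 1.0
    tails: int = 2

    def __post_init__(self) -> None:
        if self.effect_size_d <= 0:
            raise ValueError("effect size d must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.allocation_ratio <= 0:
            raise ValueError("allocation ratio must be positive")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


@dataclass
class CorrelationResult:
    """A (partial) correlation between a network attribute and a clinical variable."""

    attribute_label: str
    clinical_label: str
    method: str
    r: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")


# ---------------------------------------------------------------------------
# two-sample location tests

def two_sample_t(x, y) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test.

    Returns ``(t, df, p)`` with df = n1 + n2 - 2 and a two-sided p from
    the central t distribution.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), df, float(p)


def t_from_summary(mean1: float, sd1: float, n1: int,
                   mean2: float, sd2: float, n2: int) -> tuple[float, int, float]:
    """Pooled two-sample t from printed summary statistics (mean, SD, n)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                    equal_var=True)
    return float(t), df, float(p)


def p_from_t(t: float, df: int) -> float:
    """Two-sided p-value of a central t statistic: 2 * (1 - F_t(|t|; df))."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * sps.t.sf(abs(t), df))


# ---------------------------------------------------------------------------
# categorical and rank tests

def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test (two-sided); companion for small expected counts."""
    odds, p = sps.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U.

    Uses the exact null distribution when ``n1*n2 <= 400`` and the data are
    tie-free, otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs at least 1 value")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# multiplicity

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# correlations

def partial_pearson(x, y, covariates=None, *,
                    attribute_label: str = "x",
                    clinical_label: str = "y",
                    covariate_labels: list[str] | None = None) -> CorrelationResult:
    """Pearson correlation of x and y after residualizing both on covariates.

    Both variables are regressed (with intercept) on the covariate matrix by
    least squares; the partial r is the Pearson correlation of the residuals
    and its p-value uses ``t = r * sqrt((n - 2 - q) / (1 - r^2))`` with q the
    number of covariates.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, float))
        if Z.shape[0] != n:
            Z = Z.T
    q = Z.shape[1]
    if n <= q + 2:
        raise ValueError("need n > number of covariates + 2")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    dfree = n - 2 - q
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dfree / (1.0 - r * r))
        p = p_from_t(t, dfree)
    return CorrelationResult(
        attribute_label=attribute_label, clinical_label=clinical_label,
        method="pearson_partial" if q else "pearson",
        r=r, p=p, n=n,
        covariates=list(covariate_labels or [f"z{i}" for i in range(q)]),
    )


def spearman(x, y, *, attribute_label: str = "x",
             clinical_label: str = "y") -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input has no rank correlation")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(attribute_label=attribute_label,
                             clinical_label=clinical_label,
                             method="spearman", r=float(rho), p=float(p),
                             n=x.size)


# ---------------------------------------------------------------------------
# power / sample size

def power_two_sample_t(d: float, n1: int, n2: int, alpha: float = 0.05,
                       tails: int = 2) -> float:
    """Exact power of the two-sample t-test at effect size d (Cohen).

    The test statistic under the alternative follows a noncentral t with
    noncentrality delta = d * sqrt(n1*n2/(n1+n2)) and df = n1 + n2 - 2.
    """
    df = n1 + n2 - 2
    delta = d * np.sqrt(n1 * n2 / (n1 + n2))
    if tails == 2:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(tcrit, df, delta) + sps.nct.cdf(-tcrit, df, delta))
    tcrit = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tcrit, df, delta))


def required_sample_size(spec: PowerSpec) -> int:
    """Smallest n per group (group 1) achieving the requested power.

    Searches n1 = 2, 3, ... with n2 = round(ratio * n1) and stops at the
    first n whose exact noncentral-t power reaches ``spec.power``.
    """
    n1 = 2
    while True:
        n2 = max(2, round(spec.allocation_ratio * n1))
        achieved = power_two_sample_t(spec.effect_size_d, n1, n2,
                                      spec.alpha, spec.tails)
        if achieved >= spec.power:
            return n1
        n1 += 1
        if n1 > 10_000_000:
            raise ValueError("effect too small: required n exceeds 1e7")
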