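"""Cross-sectional test battery.

Welch's unequal-variance t test (from raw data or printed summary
statistics), Pearson chi-square and Fisher's exact test for contingency
tables, Kruskal-Wallis rank ANOVA, Spearman rank correlation, a
Monte-Carlo Lilliefors normality test, and Bonferroni familywise
control.  Standard tests delegate to scipy.stats; the chi-square uses
no continuity correction, which is what reproduces the reported
categorical statistics exactly.  Reported summary tables describe the
categorical tests as Fisher's exact while printing Pearson chi-square
values; both are therefore reported for 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import PdmorphError

__all__ = [
    "SummaryStats",
    "TestResult",
    "welch_t",
    "welch_t_from_summary",
    "pearson_chi2",
    "fisher_exact_2x2",
    "kruskal_wallis",
    "spearman",
    "lilliefors",
    "bonferroni",
]


class DomainError(PdmorphError):
    pass


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError("sd must be non-negative")
        if self.n < 2:
            raise DomainError("n must be at least 2")


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float | tuple | None
    p: float
    method: str


def welch_t_from_summary(a: SummaryStats, b: SummaryStats) -> TestResult:
    """Unpaired two-sample t test for unequal variances from summaries."""
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    se2 = a.sd**2 / a.n + b.sd**2 / b.n
    df = se2**2 / (
        (a.sd**2 / a.n) ** 2 / (a.n - 1) + (b.sd**2 / b.n) ** 2 / (b.n - 1)
    )
    return TestResult("t", float(res.statistic), float(df), float(res.pvalue), "welch")


def welch_t(a, b) -> TestResult:
    """Welch t test from raw samples (equivalent to the summary form)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each sample needs n >= 2")
    return welch_t_from_summary(
        SummaryStats(a.mean(), a.std(ddof=1), len(a)),
        SummaryStats(b.mean(), b.std(ddof=1), len(b)),
    )


def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DomainError("contingency table must be at least 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise DomainError("contingency table must hold integer counts")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise DomainError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DomainError("all row and column margins must be positive")
    return t


def pearson_chi2(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    t = _check_table(table)
    res = stats.chi2_contingency(t, correction=False)
    return TestResult("chi2", float(res.statistic), float(res.dof), float(res.pvalue), "pearson")


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test; non-2x2 tables fall back to chi-square."""
    t = _check_table(table)
    if t.shape != (2, 2):
        return pearson_chi2(t)
    res = stats.fisher_exact(t, alternative="two-sided")
    return TestResult("odds_ratio", float(res.statistic), None, float(res.pvalue), "fisher_exact")


def kruskal_wallis(samples) -> TestResult:
    """Kruskal-Wallis H with mid-rank ties and chi-square p-value.

    Groups of identical constant values (zero rank variance) give H = 0
    and p = 1 rather than an error.
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise DomainError("need >= 2 groups with >= 1 observation each")
    if sum(len(g) for g in groups) < 3:
        raise DomainError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return TestResult("H", 0.0, float(len(groups) - 1), 1.0, "kruskal-wallis")
    res = stats.kruskal(*groups)
    return TestResult("H", float(res.statistic), float(len(groups) - 1),
                      float(res.pvalue), "kruskal-wallis")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DomainError("need paired samples with n >= 3")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise DomainError("zero rank variance: correlation undefined")
    res = stats.spearmanr(x, y)
    return TestResult("rho", float(res.statistic), float(len(x) - 2),
                      float(res.pvalue), "spearman")


def _ks_normal_distance(x: np.ndarray) -> float:
    """KS distance between the ECDF and Normal(mean-hat, sd-hat)."""
    n = len(x)
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = stats.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def lilliefors(x, n_mc: int = 10_000, seed: int = 0) -> TestResult:
    """Lilliefors normality test with a Monte-Carlo null distribution.

    The composite null (normal with estimated mean and SD) makes the KS
    distance's distribution non-standard; the p-value is estimated by
    simulating ``n_mc`` standard-normal samples of the same size under a
    fixed seed, so results are reproducible without lookup tables.  The
    statistic is invariant to affine transforms of the data.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise DomainError("need n >= 5")
    if x.std(ddof=1) == 0:
        raise DomainError("zero variance sample")
    d = _ks_normal_distance(x)

    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_mc, n))
    z = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    cdf = stats.norm.cdf(z)
    grid = np.arange(1, n + 1) / n
    d_null = np.maximum((grid - cdf).max(axis=1), (cdf - (grid - 1 / n)).max(axis=1))
    p = float((np.count_nonzero(d_null >= d) + 1) / (n_mc + 1))
    return TestResult("D", d, None, p, f"lilliefors-mc({n_mc})")


def bonferroni(p_values, m: int | None = None, alpha: float = 0.05):
    """Bonferroni adjustment: min(1, p*m) and significance flags at alpha."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    adjusted = np.minimum(p * m, 1.0)
    return adjusted, adjusted < alpha
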