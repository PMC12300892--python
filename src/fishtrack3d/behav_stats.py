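"""Nonparametric group-comparison chain for binned speed series.

The procedure mirrors the standard workflow for movement data that fail a
normality screen: a one-sample Kolmogorov-Smirnov test against a
moment-matched normal per group, a tie-corrected Kruskal-Wallis test
across groups, and — only when Kruskal-Wallis is significant — the Dunn
post hoc test with Bonferroni correction to locate the differing pairs.

All rank statistics use mid-ranks for ties, with tie corrections in both
the Kruskal-Wallis H denominator and the Dunn variance.  The plain KS test
with estimated mean and standard deviation is anticonservative (the
Lilliefors effect); a seeded Monte-Carlo Lilliefors variant is available
via ``method="monte-carlo"``.

Binned speeds from a single recording are serially autocorrelated, which
the rank tests' independence assumption ignores; ``compare_groups``
surfaces a lag-1 autocorrelation diagnostic per group without altering
the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinematics import SpeedSeries


@dataclass
class KSResult:
    """One-sample Kolmogorov-Smirnov test against a fitted normal."""

    D: float
    p_value: float
    n: int
    reference: str = "normal, moment-matched"


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis H test across k groups."""

    H: float
    df: int
    p_value: float
    N: int
    group_sizes: list[int]
    mean_ranks: list[float]
    tie_correction: float


@dataclass
class DunnMatrix:
    """Pairwise Dunn z statistics and multiplicity-adjusted p-values."""

    z: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    correction: str
    m: int


@dataclass
class GroupComparisonReport:
    """Full statistics-chain output for a set of speed series."""

    group_labels: list[str]
    alpha: float
    ks: list[KSResult]
    kw: KWResult
    dunn: DunnMatrix | None
    labels: list[list[str]] | None
    lag1_autocorrelation: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "group_labels": self.group_labels,
            "alpha": self.alpha,
            "ks": [
                {"D": r.D, "p_value": r.p_value, "n": r.n, "reference": r.reference}
                for r in self.ks
            ],
            "kruskal_wallis": {
                "H": self.kw.H, "df": self.kw.df, "p_value": self.kw.p_value,
                "N": self.kw.N, "group_sizes": self.kw.group_sizes,
                "mean_ranks": self.kw.mean_ranks,
            },
            "lag1_autocorrelation": self.lag1_autocorrelation,
        }
        if self.dunn is not None:
            out["dunn"] = {
                "z": self.dunn.z.tolist(),
                "p_raw": self.dunn.p_raw.tolist(),
                "p_adjusted": self.dunn.p_adjusted.tolist(),
                "correction": self.dunn.correction,
                "m": self.dunn.m,
            }
            out["labels"] = self.labels
        return out


def ks_normality(
    sample,
    method: str = "asymptotic",
    n_sim: int = 2000,
    seed: int = 0,
) -> KSResult:
    """One-sample KS test of normality with moment-matched parameters.

    ``D`` is the sup distance between the empirical CDF and the normal CDF
    with the sample's mean and (n-1) standard deviation.  The default
    p-value comes from the asymptotic Kolmogorov distribution of
    ``sqrt(n) * D`` — anticonservative because the parameters are
    estimated; ``method="monte-carlo"`` calibrates the null by simulation
    (Lilliefors) instead.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 8:
        raise ValueError("KS normality test requires n >= 8")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("sample has zero variance")
    D = _ks_statistic(x, x.mean(), sd)
    if method == "asymptotic":
        p = float(stats.kstwobign.sf(np.sqrt(n) * D))
    elif method == "monte-carlo":
        rng = np.random.default_rng(seed)
        null = np.empty(n_sim)
        for i in range(n_sim):
            y = np.sort(rng.standard_normal(n))
            null[i] = _ks_statistic(y, y.mean(), y.std(ddof=1))
        p = float((1 + np.sum(null >= D)) / (n_sim + 1))
    else:
        raise ValueError("method must be 'asymptotic' or 'monte-carlo'")
    return KSResult(D=float(D), p_value=p, n=int(n))


def _ks_statistic(x_sorted: np.ndarray, mu: float, sd: float) -> float:
    n = x_sorted.size
    cdf = stats.norm.cdf((x_sorted - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def _pooled_ranks(groups: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray], float, int]:
    """Mid-ranks per group plus the tie-correction sum ``sum(t^3 - t)``."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled, method="average")
    out = []
    start = 0
    for g in groups:
        out.append(ranks[start:start + len(g)])
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    return pooled, out, tie_sum, len(pooled)


def kruskal_wallis(groups: list) -> KWResult:
    """Tie-corrected Kruskal-Wallis test over k >= 2 samples.

    ``H = [12/(N(N+1)) * sum(n_i * Rbar_i^2) - 3(N+1)] / C`` with the tie
    correction ``C = 1 - sum(t^3 - t)/(N^3 - N)``; the p-value uses the
    chi-square approximation with k-1 degrees of freedom.  Fully tied data
    (C = 0) are defined as H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    _, rank_groups, tie_sum, N = _pooled_ranks(groups)
    if N < 3:
        raise ValueError("need at least 3 observations in total")
    mean_ranks = [float(r.mean()) for r in rank_groups]
    sizes = [len(g) for g in groups]
    correction = 1.0 - tie_sum / (N**3 - N)
    df = len(groups) - 1
    if correction == 0.0:  # every observation identical
        return KWResult(H=0.0, df=df, p_value=1.0, N=N, group_sizes=sizes,
                        mean_ranks=mean_ranks, tie_correction=0.0)
    h_raw = 12.0 / (N * (N + 1)) * sum(
        n_i * rbar**2 for n_i, rbar in zip(sizes, mean_ranks)
    ) - 3.0 * (N + 1)
    H = h_raw / correction
    H = max(H, 0.0)  # guard tiny negative rounding at H ~ 0
    p = float(stats.chi2.sf(H, df))
    return KWResult(H=float(H), df=df, p_value=p, N=N, group_sizes=sizes,
                    mean_ranks=mean_ranks, tie_correction=float(correction))


def dunn_posthoc(groups: list, correction: str = "bonferroni") -> DunnMatrix:
    """Dunn's pairwise post hoc test on pooled mid-ranks.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - sum(t^3-t)/(12(N-1))]
    * (1/n_i + 1/n_j))``, two-sided normal p-values, Bonferroni-adjusted
    by the number of pairs ``m = k(k-1)/2`` and capped at 1.  The matrix
    is symmetric with a unit diagonal.
    """
    if correction != "bonferroni":
        raise ValueError("only the Bonferroni correction is supported")
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    _, rank_groups, tie_sum, N = _pooled_ranks(groups)
    mean_ranks = np.array([r.mean() for r in rank_groups])
    sizes = np.array([len(g) for g in groups], dtype=float)
    m = k * (k - 1) // 2
    variance_core = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    z = np.zeros((k, k))
    p_raw = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if variance_core <= 0:  # fully tied data: no evidence of difference
                zij = 0.0
            else:
                se = np.sqrt(variance_core * (1.0 / sizes[i] + 1.0 / sizes[j]))
                zij = (mean_ranks[i] - mean_ranks[j]) / se
            z[i, j] = zij
            z[j, i] = -zij
            p = 2.0 * stats.norm.sf(abs(zij))
            p_raw[i, j] = p_raw[j, i] = p
    p_adj = np.minimum(1.0, m * p_raw)
    np.fill_diagonal(p_adj, 1.0)
    np.fill_diagonal(p_raw, 1.0)
    return DunnMatrix(z=z, p_raw=p_raw, p_adjusted=p_adj, correction="bonferroni", m=m)


def lag1_autocorrelation(values) -> float:
    """Lag-1 Pearson autocorrelation of a series (NaN for n < 3)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.std() == 0:
        return float("nan")
    return float(np.corrcoef(v[:-1], v[1:])[0, 1])


def compare_groups(series: list[SpeedSeries], alpha: float = 0.05) -> GroupComparisonReport:
    """Run the full chain on per-group binned speeds.

    KS normality is reported per group; Kruskal-Wallis compares all
    groups; the Dunn matrix (with "Difference"/"No difference" labels at
    ``alpha``) is produced only when Kruskal-Wallis is significant.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 speed series")
    groups = [s.values for s in series]
    labels_g = [s.group_label for s in series]
    ks = [ks_normality(g) for g in groups]
    kw = kruskal_wallis(groups)
    dunn = None
    labels = None
    if kw.p_value < alpha:
        dunn = dunn_posthoc(groups)
        k = len(groups)
        labels = [
            [
                "X" if i == j else
                ("Difference" if dunn.p_adjusted[i, j] < alpha else "No difference")
                for j in range(k)
            ]
            for i in range(k)
        ]
    return GroupComparisonReport(
        group_labels=labels_g,
        alpha=alpha,
        ks=ks,
        kw=kw,
        dunn=dunn,
        labels=labels,
        lag1_autocorrelation=[lag1_autocorrelation(g) for g in groups],
    )
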