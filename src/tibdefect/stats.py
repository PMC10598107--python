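"""Ordinal agreement and correlation statistics for grade data.

Covers the analysis set used to compare grading methods on the ordinal AORI
scale (I = 1 ... III = 4): K x K contingency tables, unweighted Cohen's kappa
with the Landis–Koch interpretation, Spearman rank correlation with midranks
for ties, ordinal median/IQR, the Friedman test over matched methods with
pairwise Wilcoxon signed-rank post-hocs, the Kruskal–Wallis test with Dunn
post-hocs, and a Fisher-z sensitivity power analysis for Spearman
correlations.

Large-sample approximations are used throughout for p-values (normal,
chi-square, t); exact small-sample p-values are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

#: Landis–Koch agreement bands, upper edge inclusive
LANDIS_KOCH_BANDS = (
    (0.00, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def landis_koch(kappa: float) -> str:
    """Interpretation band of a kappa value (upper band edges inclusive)."""
    if kappa <= 0:
        return "poor"
    for upper, name in LANDIS_KOCH_BANDS[1:]:
        if kappa <= upper + 1e-12:
            return name
    return "almost perfect"


@dataclass
class ContingencyTable:
    """K x K cross-tabulation of two ordinal grade vectors."""

    counts: np.ndarray
    levels: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.levels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("empty table")
        if k < 2:
            raise ValueError("need at least 2 levels")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Reconstruct the per-subject (row, col) grade vectors."""
        a, b = [], []
        for i, gi in enumerate(self.levels):
            for j, gj in enumerate(self.levels):
                a.extend([gi] * self.counts[i, j])
                b.extend([gj] * self.counts[i, j])
        return np.array(a), np.array(b)


def build_table(grades_a, grades_b, levels=(1, 2, 3, 4)) -> ContingencyTable:
    """Cross-tabulate two equal-length ordinal vectors."""
    a = np.asarray(grades_a, dtype=int)
    b = np.asarray(grades_b, dtype=int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("grade vectors must be non-empty and of equal length")
    lset = set(levels)
    bad = (set(a.tolist()) | set(b.tolist())) - lset
    if bad:
        raise ValueError(f"grades outside levels {levels}: {sorted(bad)}")
    idx = {g: i for i, g in enumerate(levels)}
    counts = np.zeros((len(levels), len(levels)), dtype=int)
    for x, y in zip(a, b):
        counts[idx[x], idx[y]] += 1
    return ContingencyTable(counts, tuple(levels))


@dataclass
class AgreementResult:
    """Cohen's kappa with its components and interpretation."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    interpretation: str
    se0: float
    p_value: float


def cohens_kappa(table: ContingencyTable) -> AgreementResult:
    """Unweighted Cohen's kappa of a square contingency table.

    ``p_o`` is the diagonal proportion, ``p_e`` the chance agreement from the
    margins; the p-value is the large-sample normal approximation under the
    null kappa = 0.
    """
    t = table.counts.astype(float)
    n = t.sum()
    po = np.trace(t) / n
    r = t.sum(axis=1) / n
    c = t.sum(axis=0) / n
    pe = float(r @ c)
    if abs(1.0 - pe) < 1e-15:
        raise ZeroDivisionError(
            "degenerate table: chance agreement is 1, kappa undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss' standard error under the null hypothesis of chance agreement
    se0 = np.sqrt(
        (pe + pe**2 - float(np.sum(r * c * (r + c)))) / (n * (1.0 - pe) ** 2)
    )
    p = 2.0 * sps.norm.sf(abs(kappa) / se0) if se0 > 0 else np.nan
    return AgreementResult(
        kappa=float(kappa),
        observed_agreement=float(po),
        expected_agreement=pe,
        interpretation=landis_koch(float(kappa)),
        se0=float(se0),
        p_value=float(p),
    )


def spearman_tied(grades_a, grades_b) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties, and two-sided t p-value.

    Equivalent to the Pearson product-moment correlation of the midrank
    vectors.
    """
    a = np.asarray(grades_a, dtype=float)
    b = np.asarray(grades_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two vectors of equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroDivisionError("zero variance: correlation undefined")
    rho, p = sps.spearmanr(a, b)
    return float(rho), float(p)


def ordinal_median_iqr(grades) -> tuple[int, int, int]:
    """(median, Q1, Q3) of an ordinal vector as actual grade values.

    Quantiles use the closest-observation rule (Hyndman–Fan type 3), which
    always returns an observed grade.
    """
    g = np.asarray(grades)
    if g.size == 0:
        raise ValueError("empty grade vector")
    q1, med, q3 = np.quantile(g, [0.25, 0.5, 0.75], method="closest_observation")
    return int(med), int(q1), int(q3)


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    #: {(col_i, col_j): (wilcoxon W, bonferroni-adjusted p)}
    posthoc: dict = field(default_factory=dict)


def friedman_test(matched: np.ndarray, posthoc: bool = True) -> FriedmanResult:
    """Friedman chi-square over an n x k matrix of matched ordinal scores.

    Within-row midranks with tie correction; post-hoc pairwise Wilcoxon
    signed-rank tests with Bonferroni adjustment. All-constant rows give
    statistic 0 and p = 1.
    """
    m = np.asarray(matched, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise ValueError("need an n x k matrix with n >= 2 and k >= 3")
    cols = [m[:, j] for j in range(m.shape[1])]
    if all(np.ptp(row) == 0 for row in m):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(*cols)
    ph = {}
    if posthoc:
        npairs = m.shape[1] * (m.shape[1] - 1) // 2
        for i, j in combinations(range(m.shape[1]), 2):
            d = m[:, i] - m[:, j]
            if np.all(d == 0):
                ph[(i, j)] = (0.0, 1.0)
                continue
            w, pw = sps.wilcoxon(m[:, i], m[:, j], zero_method="wilcox")
            ph[(i, j)] = (float(w), float(min(1.0, pw * npairs)))
    return FriedmanResult(float(stat), float(p), ph)


@dataclass
class KruskalResult:
    statistic: float
    p_value: float
    #: {(group_i, group_j): (Dunn z, bonferroni-adjusted p)}
    posthoc: dict = field(default_factory=dict)


def kruskal_wallis(groups, posthoc: bool = True) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis H with Dunn pairwise post-hoc comparisons.

    Dunn's z statistics use the pooled midranks with tie correction and
    Bonferroni adjustment over all group pairs.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("need at least two non-empty groups")
    if np.ptp(np.concatenate(gs)) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*gs)
    ph = {}
    if posthoc:
        pooled = np.concatenate(gs)
        ranks = sps.rankdata(pooled)
        n = pooled.size
        # tie correction for the Dunn variance
        _, t_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(t_counts**3 - t_counts)) / (12.0 * (n - 1))
        sizes = [g.size for g in gs]
        offsets = np.cumsum([0] + sizes)
        mean_ranks = [
            ranks[offsets[i]: offsets[i + 1]].mean() for i in range(len(gs))
        ]
        npairs = len(gs) * (len(gs) - 1) // 2
        for i, j in combinations(range(len(gs)), 2):
            var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            if var <= 0:
                ph[(i, j)] = (0.0, 1.0)
                continue
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            pz = 2.0 * sps.norm.sf(abs(z))
            ph[(i, j)] = (float(z), float(min(1.0, pz * npairs)))
    return KruskalResult(float(h), float(p), ph)


def power_at(n: int, rho: float, alpha: float = 0.05) -> float:
    """Power of a two-sided Spearman test at effect ``rho``, Fisher-z approximation."""
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.cdf(np.arctanh(rho) * np.sqrt(n - 3) - z_a))


def spearman_sensitivity(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Minimal detectable Spearman correlation at given alpha and power.

    Inverse of :func:`power_at` via the Fisher z transform:
    ``tanh((z_{1-alpha/2} + z_{power}) / sqrt(n - 3))``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    return float(np.tanh((z_a + z_b) / np.sqrt(n - 3)))


def monte_carlo_power(
    n: int, rho: float, alpha: float = 0.05, n_rep: int = 10_000, seed: int = 0
) -> float:
    """Empirical power of the Spearman test on bivariate-normal samples.

    ``rho`` is the population *Spearman* correlation; samples are drawn with
    the Pearson correlation ``2 sin(pi rho / 6)`` (Greiner's relation), which
    yields that Spearman correlation under bivariate normality.
    """
    rng = np.random.default_rng(seed)
    rho_p = 2.0 * np.sin(np.pi * rho / 6.0)
    cov = np.array([[1.0, rho_p], [rho_p, 1.0]])
    hits = 0
    for _ in range(n_rep):
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
        _, p = sps.spearmanr(xy[:, 0], xy[:, 1])
        hits += p < alpha
    return hits / n_rep
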