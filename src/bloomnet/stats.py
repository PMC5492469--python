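"""Distance-based community comparison and environmental screening.

PERMANOVA partitions the squared inter-sample distances into among- and
within-group sums of squares (pseudo-F, R^2); MRPP compares the weighted mean
within-group distance delta to its permutation distribution (chance-corrected
A).  Both report permutation p-values with the (1+b)/(1+m) estimator, or the
exact enumeration p when the number of distinct relabelings does not exceed
the requested permutation count.  The single-factor screen is a one-term
distance-based linear model (Gower-centered inner-product matrix, continuous
predictor) run one environmental variable at a time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistanceMatrix",
    "PermutationTestResult",
    "TaxonComparison",
    "distance_matrix",
    "permanova",
    "mrpp",
    "single_factor_screen",
    "taxon_wise_comparison",
    "spearman_screen",
]

_METRICS = ("bray_curtis", "euclidean")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        self.d = d


@dataclass
class PermutationTestResult:
    method: str                     # "permanova" | "mrpp" | "single_factor"
    statistic_name: str             # "pseudo-F" | "delta"
    statistic: float
    effect_name: str                # "R2" | "A"
    effect: float
    n_permutations: int
    p_value: float
    seed: int | None
    exhaustive: bool = False


def distance_matrix(abundances: np.ndarray, sample_ids: list[str], metric: str) -> DistanceMatrix:
    """Pairwise distances between sample columns.

    ``abundances`` is taxa x samples; pass column-normalized proportions for
    bray_curtis (bc(x,y) = sum|x-y| / sum(x+y)).
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    x = np.asarray(abundances, dtype=float).T  # samples in rows for pdist
    if x.shape[0] != len(sample_ids):
        raise ValueError("abundance matrix columns must match sample_ids")
    scipy_name = "braycurtis" if metric == "bray_curtis" else "euclidean"
    d = squareform(pdist(x, metric=scipy_name))
    return DistanceMatrix(list(sample_ids), d, metric)


def _count_distinct_relabelings(groups: np.ndarray) -> int:
    n = len(groups)
    total = math.factorial(n)
    for _, count in zip(*np.unique(groups, return_counts=True)):
        total //= math.factorial(int(count))
    return total


def _multiset_permutations(items: list):
    """Yield every distinct ordering of ``items`` (lexicographic)."""
    items = sorted(items)
    n = len(items)

    def rec(remaining: list, prefix: list):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        prev = object()
        for i, it in enumerate(remaining):
            if it == prev:
                continue
            prev = it
            yield from rec(remaining[:i] + remaining[i + 1:], prefix + [it])

    yield from rec(items, [])


def _permutation_p(observed: float, statistic, groups: np.ndarray,
                   n_permutations: int, seed: int | None,
                   larger_is_extreme: bool = True):
    """Permutation p-value for a label-based statistic.

    Enumerates all distinct relabelings when there are no more of them than
    ``n_permutations`` (exact p = proportion at least as extreme, identity
    included); otherwise samples relabelings and uses (1+b)/(1+m).
    Returns (p, permuted statistics, exhaustive flag).
    """
    def extreme(s: float) -> bool:
        return s >= observed - 1e-12 if larger_is_extreme else s <= observed + 1e-12

    n_distinct = _count_distinct_relabelings(groups)
    if n_distinct <= n_permutations:
        perm_stats = [statistic(np.array(p)) for p in _multiset_permutations(list(groups))]
        b = sum(extreme(s) for s in perm_stats)
        return b / n_distinct, perm_stats, True
    rng = np.random.default_rng(seed)
    perm_stats = []
    b = 0
    for _ in range(n_permutations):
        s = statistic(rng.permutation(groups))
        perm_stats.append(s)
        b += extreme(s)
    return (1 + b) / (1 + n_permutations), perm_stats, False


def _check_groups(dist: DistanceMatrix, groups) -> np.ndarray:
    groups = np.asarray(groups)
    if groups.shape[0] != len(dist.sample_ids):
        raise ValueError("one group label per sample required")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 1:
        raise ValueError("every group needs at least 1 sample")
    return groups


def _permanova_f(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances for a grouping vector."""
    n = d2.shape[0]
    labels = np.unique(groups)
    a = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for lab in labels:
        idx = np.flatnonzero(groups == lab)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    if n - a == 0 or ss_within == 0:
        f = float("inf") if ss_among > 0 else 0.0
    else:
        f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, r2


def permanova(dist: DistanceMatrix, groups, n_permutations: int = 999,
              seed: int | None = None) -> PermutationTestResult:
    """Permutational multivariate ANOVA (one-way) on a distance matrix."""
    groups = _check_groups(dist, groups)
    d2 = dist.d ** 2
    f_obs, r2 = _permanova_f(d2, groups)
    p, _, exhaustive = _permutation_p(
        f_obs, lambda g: _permanova_f(d2, g)[0], groups, n_permutations, seed
    )
    return PermutationTestResult("permanova", "pseudo-F", f_obs, "R2", r2,
                                 n_permutations, p, seed, exhaustive)


def _mrpp_delta(d: np.ndarray, groups: np.ndarray) -> float:
    n = d.shape[0]
    delta = 0.0
    for lab in np.unique(groups):
        idx = np.flatnonzero(groups == lab)
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            mean_within = sub[np.triu_indices(len(idx), k=1)].mean()
            delta += (len(idx) / n) * mean_within
    return delta


def mrpp(dist: DistanceMatrix, groups, n_permutations: int = 999,
         seed: int | None = None) -> PermutationTestResult:
    """Multiple-response permutation procedure: weighted within-group delta.

    Small delta means tight groups; A = 1 - delta/mean(permuted delta) is the
    chance-corrected within-group agreement.
    """
    groups = _check_groups(dist, groups)
    delta_obs = _mrpp_delta(dist.d, groups)
    p, perm_deltas, exhaustive = _permutation_p(
        delta_obs, lambda g: _mrpp_delta(dist.d, g), groups, n_permutations,
        seed, larger_is_extreme=False,
    )
    expected = float(np.mean(perm_deltas))
    a_stat = 1.0 - delta_obs / expected if expected > 0 else 0.0
    return PermutationTestResult("mrpp", "delta", delta_obs, "A", a_stat,
                                 n_permutations, p, seed, exhaustive)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d ** 2
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


def single_factor_screen(dist: DistanceMatrix, variable_values,
                         n_permutations: int = 999,
                         seed: int | None = None) -> PermutationTestResult:
    """Distance-based pseudo-F for a single continuous predictor.

    One-term linear model on the Gower-centered inner-product matrix; the
    p-value permutes the predictor across samples.
    """
    x = np.asarray(variable_values, dtype=float)
    if x.shape[0] != len(dist.sample_ids):
        raise ValueError("one value per sample required")
    if np.ptp(x) == 0:
        raise ValueError("constant variable cannot be screened")
    n = x.shape[0]
    g = _gower_center(dist.d)
    ss_total = float(np.trace(g))

    def pseudo_f(values: np.ndarray) -> float:
        design = np.column_stack([np.ones(n), values])
        hat = design @ np.linalg.pinv(design)
        ss_model = float(np.trace(hat @ g))
        ss_resid = ss_total - ss_model
        if ss_resid <= 0:
            return float("inf") if ss_model > 0 else 0.0
        return (ss_model / 1.0) / (ss_resid / (n - 2))

    f_obs = pseudo_f(x)
    r2 = float(np.trace(np.column_stack([np.ones(n), x]) @ np.linalg.pinv(np.column_stack([np.ones(n), x])) @ g)) / ss_total if ss_total else 0.0
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        if pseudo_f(rng.permutation(x)) >= f_obs - 1e-12:
            b += 1
    p = (1 + b) / (1 + n_permutations)
    return PermutationTestResult("single_factor", "pseudo-F", f_obs, "R2", r2,
                                 n_permutations, p, seed, False)


@dataclass
class TaxonComparison:
    taxon: str
    mean_a: float
    mean_b: float
    direction: str          # "higher in A" | "lower in A" | "equal"
    p_value: float
    p_adjusted: float
    significant_raw: bool = False
    significant_adjusted: bool = False


def taxon_wise_comparison(table_a, table_b, alpha: float = 0.05) -> list[TaxonComparison]:
    """Per-taxon Welch t-test of relative abundances between two tables.

    Both tables must share the same taxon set (matched by OTU id).  Reports
    the raw two-sided p, the Benjamini-Hochberg adjusted p and the direction
    of the difference; a taxon with zero variance on both sides and equal
    means gets p = 1 by convention.
    """
    if set(table_a.otu_ids) != set(table_b.otu_ids):
        raise ValueError("taxon sets differ between the two tables")
    if table_a.n_samples < 2 or table_b.n_samples < 2:
        raise ValueError("need at least 2 samples per side")
    from .preprocess import relative_abundance

    rel_a = relative_abundance(table_a)
    rel_b = relative_abundance(table_b)
    index_b = {o: i for i, o in enumerate(table_b.otu_ids)}
    results = []
    p_values = []
    for i, taxon in enumerate(table_a.otu_ids):
        a = rel_a[i]
        b = rel_b[index_b[taxon]]
        if a.var() == 0 and b.var() == 0:
            p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        else:
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        ma, mb = float(a.mean()), float(b.mean())
        if np.isclose(ma, mb):
            direction = "equal"
        else:
            direction = "higher in A" if ma > mb else "lower in A"
        results.append(TaxonComparison(taxon, ma, mb, direction, p, float("nan")))
        p_values.append(p)
    rejected, p_adj, *_ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    for rec, pa, rej in zip(results, p_adj, rejected):
        rec.p_adjusted = float(pa)
        rec.significant_raw = rec.p_value < alpha and rec.direction != "equal"
        rec.significant_adjusted = bool(rej) and rec.direction != "equal"
    return results


def spearman_screen(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with large-sample p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
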