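"""Distance matrices, distance-decay regressions, PERMANOVA, and group contrasts.

The distance-decay relationship (DDR) — the decline of community
similarity with geographic distance — is fitted as an ordinary least
squares regression of log10(similarity) on log10(distance).  PERMANOVA
partitions the sum of squared distances into within- and between-group
components and assesses the pseudo-F statistic by label permutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _scipy_braycurtis, pdist, squareform
from statsmodels.stats.multitest import multipletests

from .community_profiling import AbundanceTable
from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedDistanceError,
)

__all__ = [
    "DdrFit",
    "GroupContrast",
    "haversine_km",
    "bray_curtis",
    "distance_pairs",
    "ddr_fit",
    "permanova",
    "rank_sum_contrast",
    "bh_adjust",
    "genome_size_regression",
]

EARTH_RADIUS_KM = 6371.0


# ======================================================================
# distances
# ======================================================================

def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a sphere of radius 6,371 km.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    for lat in (lat1, lat2):
        if np.any(np.abs(np.asarray(lat, float)) > 90):
            raise InvalidArgumentError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(np.asarray(lon, float)) > 180):
            raise InvalidArgumentError("longitude outside [-180, 180]")
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    out = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return float(out) if np.isscalar(lat1) and np.isscalar(lat2) else out


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x < 0) or np.any(y < 0):
        raise InvalidArgumentError("abundance vectors must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise UndefinedDistanceError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(x, y))


def _dissimilarity_matrix(table: AbundanceTable, metric: str) -> np.ndarray:
    data = table.matrix.to_numpy(float).T  # samples x species
    if metric == "braycurtis":
        if np.any(data.sum(axis=1) == 0):
            raise UndefinedDistanceError("a sample with zero total abundance")
        return squareform(pdist(data, metric="braycurtis"))
    if metric == "euclidean":
        return squareform(pdist(data, metric="euclidean"))
    raise InvalidArgumentError(f"unknown metric {metric!r}")


def distance_pairs(table: AbundanceTable, metric: str = "braycurtis") -> pd.DataFrame:
    """All unordered sample pairs with geographic and community distance."""
    D = _dissimilarity_matrix(table, metric)
    meta = table.metadata.loc[list(table.matrix.columns)]
    lat = meta["latitude"].to_numpy(float)
    lon = meta["longitude"].to_numpy(float)
    samples = list(table.matrix.columns)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            rows.append({
                "sample_a": samples[i],
                "sample_b": samples[j],
                "geographic_km": haversine_km(lat[i], lon[i], lat[j], lon[j]),
                "dissimilarity": D[i, j],
            })
    return pd.DataFrame(rows)


# ======================================================================
# distance-decay regression
# ======================================================================

@dataclass
class DdrFit:
    """OLS fit of log10(similarity) on log10(distance)."""

    slope: float
    intercept: float
    r2_adjusted: float
    p_value: float
    n_pairs: int
    n_excluded: int = 0


def _adjusted_r2(r2: float, n: int, k: int = 1) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _degenerate_fit_guard(res) -> tuple[float, float, float]:
    """Constant response: slope 0, no explained variance, p-value 1."""
    if not math.isfinite(res.pvalue):
        return 0.0, 0.0, 1.0
    return float(res.slope), float(res.rvalue) ** 2, float(res.pvalue)


def ddr_fit(pairs: pd.DataFrame, metric: str = "braycurtis") -> DdrFit:
    """Distance-decay fit on log-log axes.

    Similarity is 1 - d for Bray-Curtis dissimilarity; for unbounded
    Euclidean distance the bounded monotone transform 1/(1 + d) is used.
    Pairs with zero geographic distance or non-positive similarity cannot
    be log-transformed and are excluded (their count is reported).
    """
    if metric == "braycurtis":
        sim = 1.0 - pairs["dissimilarity"].to_numpy(float)
    elif metric == "euclidean":
        sim = 1.0 / (1.0 + pairs["dissimilarity"].to_numpy(float))
    else:
        raise InvalidArgumentError(f"unknown metric {metric!r}")
    dist = pairs["geographic_km"].to_numpy(float)
    usable = (dist > 0) & (sim > 0)
    n_excluded = int((~usable).sum())
    dist, sim = dist[usable], sim[usable]
    if len(dist) < 3:
        raise InsufficientDataError("need at least 3 usable pairs for a DDR fit")
    res = stats.linregress(np.log10(dist), np.log10(sim))
    n = len(dist)
    slope, r2, p = _degenerate_fit_guard(res)
    return DdrFit(slope=slope, intercept=float(res.intercept),
                  r2_adjusted=_adjusted_r2(r2, n),
                  p_value=p, n_pairs=n, n_excluded=n_excluded)


# ======================================================================
# PERMANOVA
# ======================================================================

def permanova(distances: np.ndarray, groups, n_permutations: int = 999,
              seed: int = 0):
    """One-way PERMANOVA on a square distance matrix.

    Pseudo-F = (SS_between / (g - 1)) / (SS_within / (n - g)) from the
    standard partition SS_total = SS_within + SS_between, where
    SS_total = sum of squared distances / n and SS_within sums, per group,
    the squared within-group distances divided by the group size.  The
    p-value is (1 + #{permuted F >= observed}) / (1 + n_permutations);
    labels are permuted freely (no strata).

    Returns ``(pseudo_F, R2, p_value)``.  Verified against the
    scikit-bio implementation in the test suite.
    """
    D = np.asarray(distances, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidArgumentError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise InvalidArgumentError("distance matrix must be symmetric")
    groups = np.asarray(groups)
    n = D.shape[0]
    if len(groups) != n:
        raise InvalidArgumentError("group labels must match matrix size")
    labels, inverse = np.unique(groups, return_inverse=True)
    g = len(labels)
    if g < 2:
        raise InvalidArgumentError("need at least 2 groups")
    sizes = np.bincount(inverse)
    if np.any(sizes < 2):
        raise InvalidArgumentError("every group needs at least 2 samples")
    D2 = D ** 2
    ss_total = D2.sum() / (2 * n)
    if ss_total == 0:
        return 0.0, 0.0, 1.0  # no variation at all

    rng = np.random.default_rng(seed)
    inv_sizes = 1.0 / sizes

    def ss_within(assign: np.ndarray) -> float:
        # one-hot (g, n) @ D2 @ one-hot.T diagonal, halved
        total = 0.0
        for k in range(g):
            idx = np.where(assign == k)[0]
            total += D2[np.ix_(idx, idx)].sum() / (2 * sizes[k])
        return total

    def pseudo_f(assign: np.ndarray) -> float:
        ssw = ss_within(assign)
        ssb = ss_total - ssw
        return (ssb / (g - 1)) / (ssw / (n - g)) if ssw > 0 else math.inf

    f_obs = pseudo_f(inverse)
    # vectorized permutation nulls: indicator masks against D2
    perms = np.stack([rng.permutation(inverse) for _ in range(n_permutations)])
    ssw_perm = np.zeros(n_permutations)
    for k in range(g):
        mask = (perms == k).astype(float)          # (P, n)
        ssw_perm += np.einsum("pi,ij,pj->p", mask, D2, mask) * (inv_sizes[k] / 2.0)
    ssb_perm = ss_total - ssw_perm
    with np.errstate(divide="ignore"):
        f_perm = (ssb_perm / (g - 1)) / (ssw_perm / (n - g))
    p = (1 + int(np.sum(f_perm >= f_obs))) / (1 + n_permutations)
    r2 = (ss_total - ss_within(inverse)) / ss_total
    return float(f_obs), float(r2), float(p)


# ======================================================================
# rank-sum contrasts and multiple testing
# ======================================================================

@dataclass
class GroupContrast:
    """Mann-Whitney contrast between two groups of values."""

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_adjusted: float = float("nan")
    n_a: int = 0
    n_b: int = 0
    median_a: float = float("nan")
    median_b: float = float("nan")


def rank_sum_contrast(values_a, values_b, group_a: str = "a", group_b: str = "b",
                      alternative: str = "two-sided") -> GroupContrast:
    """Two-sample Mann-Whitney (Wilcoxon rank-sum) test.

    Uses exact enumeration when both samples have n <= 8 and no ties span
    the groups; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupContrast(group_a=group_a, group_b=group_b,
                         statistic=float(res.statistic), p_value=float(res.pvalue),
                         n_a=int(a.size), n_b=int(b.size),
                         median_a=float(np.median(a)), median_b=float(np.median(b)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genome_size_regression(range_sizes, genome_sizes):
    """OLS of genome size (Mbp) on range size; returns (slope, adj R2, p)."""
    x = np.asarray(range_sizes, float)
    y = np.asarray(genome_sizes, float)
    if x.size != y.size or x.size < 3:
        raise InvalidArgumentError("need matched vectors of length >= 3")
    res = stats.linregress(x, y)
    slope, r2, p = _degenerate_fit_guard(res)
    return slope, _adjusted_r2(r2, x.size), p
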