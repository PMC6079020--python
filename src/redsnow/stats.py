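"""Community statistics: Shannon-Wiener diversity, Bray-Curtis
dissimilarity, UPGMA dendrograms, PERMANOVA, the Mantel test and
great-circle distances.

The permutation engines (PERMANOVA, Mantel) are seeded and use the
add-one rule p = (#{permuted >= observed} + 1) / (n_perm + 1), so p is
never exactly zero and identical seeds reproduce identical results.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import braycurtis as _braycurtis, squareform

__all__ = [
    "DistanceMatrix",
    "PermutationTestResult",
    "shannon",
    "bray_curtis",
    "bray_curtis_matrix",
    "upgma",
    "upgma_newick",
    "permanova",
    "pairwise_permanova",
    "mantel",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class PermutationTestResult:
    statistic: float
    n_permutations: int
    p_value: float
    seed: int | None
    method: str = ""


def shannon(counts: Sequence[float]) -> float:
    """Shannon-Wiener index H = -sum p_i ln p_i (natural log)."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """BC = sum|x_i - y_i| / sum(x_i + y_i)."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.sum() + b.sum() == 0:
        raise ValueError("both vectors all-zero")
    return float(_braycurtis(a, b))


def bray_curtis_matrix(counts: np.ndarray, labels: Sequence[str]) -> DistanceMatrix:
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(counts[i], counts[j])
    return DistanceMatrix(list(labels), d)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(dm: DistanceMatrix) -> np.ndarray:
    """Average-linkage agglomeration (scipy linkage encoding).

    Merge heights are non-decreasing; labels are ordered, so ties resolve
    deterministically by the input (lexicographic) label order.
    """
    if len(dm.labels) < 2:
        raise ValueError("need at least two leaves")
    order = np.argsort(dm.labels, kind="stable")
    d = dm.d[np.ix_(order, order)]
    z = linkage(squareform(d, checks=False), method="average")
    # re-express leaf indices in the original label order
    remap = {i: int(orig) for i, orig in enumerate(order)}
    z = z.copy()
    for row in z:
        for k in (0, 1):
            if row[k] < len(dm.labels):
                row[k] = remap[int(row[k])]
    return z


def upgma_newick(dm: DistanceMatrix) -> str:
    """UPGMA dendrogram as a Newick string with ultrametric branch
    lengths (node height = merge distance / 2)."""
    z = upgma(dm)
    n = len(dm.labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: dm.labels[i] for i in range(n)}
    minlab = {i: dm.labels[i] for i in range(n)}
    for k, (a, b, dist, _cnt) in enumerate(z):
        a, b = int(a), int(b)
        if minlab[b] < minlab[a]:
            a, b = b, a
        h = dist / 2.0
        left = f"{node[a]}:{h - height[a]:.10g}"
        right = f"{node[b]}:{h - height[b]:.10g}"
        idx = n + k
        node[idx] = f"({left},{right})"
        height[idx] = h
        minlab[idx] = min(minlab[a], minlab[b])
    return node[n + len(z) - 1] + ";"


# ---------------------------------------------------------------------------
# Permutation tests


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Distance-based one-way pseudo-F from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ng = idx.size
        if ng > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0 or ss_within == 0:
        return math.inf if ss_among > 0 else 0.0
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """One-way PERMANOVA on a distance matrix.

    ``exhaustive=True`` enumerates all label permutations instead of
    sampling (small n only); the +1 rule then counts every enumerated
    permutation including the identity.
    """
    groups = list(groups)
    if len(groups) != len(dm.labels):
        raise ValueError("group labels do not match matrix")
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    codes = np.array([uniq.index(g) for g in groups])
    d2 = dm.d ** 2
    obs = _pseudo_f(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(len(codes)))]
        stats = [_pseudo_f(d2, codes[p], len(uniq)) for p in perms]
        # identity permutation is among the enumerated ones; apply the +1
        # rule over the full enumeration
        n_eff = len(stats)
        p = (sum(1 for s in stats if s >= obs - 1e-12)) / n_eff
        return PermutationTestResult(obs, n_eff, p, seed, "permanova-exhaustive")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(codes))
        if _pseudo_f(d2, codes[perm], len(uniq)) >= obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(obs, n_perm, p, seed, "permanova")


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    bonferroni: bool = False,
) -> dict[tuple[str, str], PermutationTestResult]:
    """One-way PERMANOVA for every pair of groups.

    Each contrast restricts the matrix to the two groups' members and runs
    a separate one-way test.  With ``bonferroni=True`` the p-values are
    multiplied by the number of contrasts (capped at 1).
    """
    groups = list(groups)
    uniq = sorted(set(groups))
    out: dict[tuple[str, str], PermutationTestResult] = {}
    contrasts = list(itertools.combinations(uniq, 2))
    for k, (g1, g2) in enumerate(contrasts):
        idx = [i for i, g in enumerate(groups) if g in (g1, g2)]
        sub = DistanceMatrix([dm.labels[i] for i in idx], dm.d[np.ix_(idx, idx)])
        res = permanova(sub, [groups[i] for i in idx], n_perm=n_perm,
                        seed=None if seed is None else seed + k)
        if bonferroni:
            res.p_value = min(1.0, res.p_value * len(contrasts))
        out[(g1, g2)] = res
    return out


def _mantel_r(v1: np.ndarray, d2: np.ndarray, idx: np.ndarray) -> float:
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    v2 = d2[np.ix_(idx, idx)][iu]
    v2 = v2 - v2.mean()
    denom = np.sqrt((v1 ** 2).sum() * (v2 ** 2).sum())
    if denom == 0:
        return 0.0
    return float((v1 * v2).sum() / denom)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "pearson",
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Mantel test of matrix correlation (one-sided, greater).

    The statistic is the Pearson (default) or Spearman correlation of the
    lower-triangle entries; the null distribution permutes rows and
    columns of the second matrix simultaneously.
    """
    if dm1.labels != dm2.labels:
        raise ValueError("distance matrices must share labels in order")
    n = len(dm1.labels)
    if n < 4:
        raise ValueError("need at least 4 objects")
    d1, d2 = dm1.d, dm2.d
    if method == "spearman":
        from scipy.stats import rankdata
        iu = np.triu_indices(n, 1)
        d1 = np.zeros_like(dm1.d)
        d2 = np.zeros_like(dm2.d)
        d1[iu] = rankdata(dm1.d[iu]); d1 += d1.T
        d2[iu] = rankdata(dm2.d[iu]); d2 += d2.T
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    iu = np.triu_indices(n, 1)
    v1 = d1[iu]
    v1 = v1 - v1.mean()
    ident = np.arange(n)
    obs = _mantel_r(v1, d2, ident)
    if exhaustive:
        stats = [
            _mantel_r(v1, d2, np.array(p))
            for p in itertools.permutations(range(n))
        ]
        p = sum(1 for s in stats if s >= obs - 1e-12) / len(stats)
        return PermutationTestResult(obs, len(stats), p, seed, f"mantel-{method}-exhaustive")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _mantel_r(v1, d2, rng.permutation(n)) >= obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(obs, n_perm, p, seed, f"mantel-{method}")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a sphere of radius 6371 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError("latitude out of range")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError("longitude out of range")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def region_distance_km(
    sites1: Sequence[tuple[float, float]], sites2: Sequence[tuple[float, float]]
) -> float:
    """Region-level distance: mean of inter-site great-circle distances."""
    ds = [
        haversine_km(a[0], a[1], b[0], b[1])
        for a in sites1 for b in sites2
    ]
    return float(np.mean(ds))
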