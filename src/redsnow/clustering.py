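"""Phylotype clustering: greedy centroid OTUs at 98% identity, 99%
furthest-neighbour (complete-linkage) clusters, and de novo chimera
detection with an abundance-skew two-segment model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import AlignmentParams, DEFAULT_PARAMS, global_align
from .reads import Phylotype

logger = logging.getLogger(__name__)

__all__ = [
    "OTU",
    "ChimeraVerdict",
    "greedy_cluster",
    "furthest_neighbour_cluster",
    "detect_chimera_denovo",
    "remove_chimeras",
    "cluster_phylotypes_to_otus",
]


@dataclass
class OTU:
    otu_id: str
    centroid: str  # phylotype_id
    members: list[str] = field(default_factory=list)
    threshold: float = 0.98


@dataclass
class ChimeraVerdict:
    query: str
    is_chimera: bool
    parent_a: str | None = None
    parent_b: str | None = None
    crossover: int | None = None
    id_model: float = 0.0
    id_best_single: float = 0.0


def _edlib_identity_upper(a: str, b: str) -> float:
    """Cheap upper-ish identity estimate from unit-cost edit distance.

    Used only as a conservative prefilter: a pair whose affine-gap overlap
    identity exceeds t has edit distance small enough that this estimate
    cannot fall below t - margin for the margins used here.
    """
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def greedy_cluster(
    phylotypes: Sequence[Phylotype],
    id_threshold: float = 0.98,
    cov_threshold: float = 0.80,
    params: AlignmentParams = DEFAULT_PARAMS,
    prefilter_margin: float | None = 0.03,
) -> list[OTU]:
    """UCLUST-style greedy centroid clustering.

    Input must be sorted abundance-descending (ties lexicographic), as
    produced by dereplication.  Each phylotype joins the *first* existing
    centroid (in creation order) with identity > ``id_threshold`` and both
    coverages > ``cov_threshold``; otherwise it founds a new centroid.

    ``prefilter_margin``: centroids whose edit-distance identity estimate
    falls below ``id_threshold - margin`` are skipped without a full
    alignment; set to None to disable the prefilter.
    """
    otus: list[OTU] = []
    centroid_seqs: list[str] = []
    for p in phylotypes:
        placed = False
        for k, otu in enumerate(otus):
            cseq = centroid_seqs[k]
            if prefilter_margin is not None:
                if _edlib_identity_upper(p.sequence, cseq) < id_threshold - prefilter_margin:
                    continue
            res = global_align(p.sequence, cseq, params)
            if (res.identity > id_threshold
                    and res.coverage_a > cov_threshold
                    and res.coverage_b > cov_threshold):
                otu.members.append(p.phylotype_id)
                placed = True
                break
        if not placed:
            otu = OTU(
                otu_id=f"OTU{len(otus) + 1:05d}",
                centroid=p.phylotype_id,
                members=[p.phylotype_id],
                threshold=id_threshold,
            )
            otus.append(otu)
            centroid_seqs.append(p.sequence)
    return otus


def furthest_neighbour_cluster(
    sequences: dict[str, str],
    id_threshold: float = 0.99,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[list[str]]:
    """Complete-linkage agglomeration on distance 1 - identity.

    Merging stops before any cluster would contain a pair with identity
    below ``id_threshold``; within every returned cluster the minimum
    pairwise identity is >= the threshold.  Labels are sorted first so the
    merge order is deterministic.
    """
    labels = sorted(sequences)
    n = len(labels)
    if n == 0:
        return []
    if n == 1:
        return [labels]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_align(sequences[labels[i]], sequences[labels[j]], params).identity
            dist[i, j] = dist[j, i] = 1.0 - ident
    z = linkage(squareform(dist, checks=False), method="complete")
    # fcluster at t: all merges with complete-linkage height <= t, i.e. every
    # within-cluster pair has distance <= t
    assign = fcluster(z, t=(1.0 - id_threshold) + 1e-12, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for lab, c in zip(labels, assign):
        clusters.setdefault(c, []).append(lab)
    return sorted(clusters.values(), key=lambda c: c[0])


# ---------------------------------------------------------------------------
# Chimera detection


def _match_profile(query: str, candidate: str) -> np.ndarray:
    """Boolean per-query-position match vector from an edit-optimal
    alignment of query against candidate."""
    res = edlib.align(query, candidate, mode="NW", task="path")
    prof = np.zeros(len(query), dtype=bool)
    qpos = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            prof[qpos:qpos + n] = True
            qpos += n
        elif ch in "XI":  # mismatch / insertion in query
            qpos += n
        # 'D' consumes candidate only
    return prof


def detect_chimera_denovo(
    query: Phylotype,
    candidates: Sequence[Phylotype],
    min_skew: float = 2.0,
    min_gain: float = 0.02,
    min_model: float = 0.98,
    max_candidates: int = 30,
) -> ChimeraVerdict:
    """Two-segment de novo chimera model.

    Candidate parents are phylotypes at least ``min_skew`` times more
    abundant than the query (PCR chimeras are rarer than their templates).
    For every ordered parent pair (A, B) and crossover position x on the
    query, the model identity is the fraction of query positions matched by
    A on [0, x) plus by B on [x, L).  The query is flagged when the best
    model beats the best single parent by at least ``min_gain`` *and*
    nearly reconstructs the query (``id_model >= min_model``): a PCR
    chimera is an exact splice of its parents, so a model that leaves >2%
    of the query unexplained indicates a merely divergent sequence, not a
    chimera.
    """
    pool = [
        c for c in candidates
        if c.phylotype_id != query.phylotype_id
        and c.total_count >= min_skew * query.total_count
    ]
    pool.sort(key=lambda c: (-c.total_count, c.sequence))
    pool = pool[:max_candidates]
    if len(pool) < 2:
        return ChimeraVerdict(query=query.phylotype_id, is_chimera=False)
    L = len(query.sequence)
    profiles = np.stack([_match_profile(query.sequence, c.sequence) for c in pool])
    single = profiles.mean(axis=1)
    best_single = float(single.max())
    # prefix[c, x] = matches of candidate c on query[:x]
    prefix = np.zeros((len(pool), L + 1), dtype=np.int64)
    np.cumsum(profiles, axis=1, out=prefix[:, 1:])
    totals = prefix[:, -1]
    # for each crossover x: best left parent and best right parent
    left_best = prefix.max(axis=0)                 # shape L+1
    left_arg = prefix.argmax(axis=0)
    suffix = totals[:, None] - prefix               # matches on query[x:]
    right_best = suffix.max(axis=0)
    right_arg = suffix.argmax(axis=0)
    model = (left_best + right_best) / L
    x = int(model.argmax())
    id_model = float(model[x])
    pa, pb = int(left_arg[x]), int(right_arg[x])
    is_chim = (pa != pb
               and id_model >= min_model
               and id_model >= best_single + min_gain
               and id_model > best_single)
    return ChimeraVerdict(
        query=query.phylotype_id,
        is_chimera=bool(is_chim),
        parent_a=pool[pa].phylotype_id if is_chim else None,
        parent_b=pool[pb].phylotype_id if is_chim else None,
        crossover=x if is_chim else None,
        id_model=id_model,
        id_best_single=best_single,
    )


def remove_chimeras(
    phylotypes: Sequence[Phylotype],
    min_skew: float = 2.0,
    min_gain: float = 0.02,
    min_model: float = 0.98,
    max_candidates: int = 30,
    min_query_count: int = 1,
) -> tuple[list[Phylotype], list[ChimeraVerdict]]:
    """Screen every phylotype against its more-abundant peers.

    ``min_query_count`` lets callers skip queries that a later stage
    removes anyway (e.g. singletons); verdicts are returned for all
    screened queries.
    """
    ordered = sorted(phylotypes, key=lambda p: (-p.total_count, p.sequence))
    verdicts: list[ChimeraVerdict] = []
    kept: list[Phylotype] = []
    for i, p in enumerate(ordered):
        if p.total_count < min_query_count:
            kept.append(p)
            continue
        v = detect_chimera_denovo(
            p, ordered[:i], min_skew=min_skew, min_gain=min_gain,
            min_model=min_model, max_candidates=max_candidates,
        )
        verdicts.append(v)
        if not v.is_chimera:
            kept.append(p)
    kept.sort(key=lambda p: (-p.total_count, p.sequence))
    return kept, verdicts


def cluster_phylotypes_to_otus(
    phylotypes: Sequence[Phylotype],
    id_threshold: float = 0.98,
    cov_threshold: float = 0.80,
    params: AlignmentParams = DEFAULT_PARAMS,
    prefilter_margin: float | None = 0.03,
) -> tuple[list[OTU], dict[str, dict[str, int]]]:
    """Greedy-cluster phylotypes and aggregate per-sample counts per OTU.

    Returns the OTU list and a mapping otu_id -> {sample_id: count}.
    """
    ordered = sorted(phylotypes, key=lambda p: (-p.total_count, p.sequence))
    otus = greedy_cluster(ordered, id_threshold, cov_threshold, params, prefilter_margin)
    by_id = {p.phylotype_id: p for p in phylotypes}
    counts: dict[str, dict[str, int]] = {}
    for otu in otus:
        agg: dict[str, int] = {}
        for pid in otu.members:
            for sid, c in by_id[pid].per_sample_counts.items():
                agg[sid] = agg.get(sid, 0) + c
        counts[otu.otu_id] = agg
    return otus, counts
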