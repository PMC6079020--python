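"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration (or direct
formula evaluation) so that the package implementations are checked
against something that shares none of their code paths.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

# ---------------------------------------------------------------------------
# Alignment: enumerate all monotone column pairings; internal gaps priced
# as affine runs (open + (L-1) * extend), end gaps free.


def _pairings(n: int, m: int):
    """All strictly increasing one-to-one pairings between [0,n) and [0,m)."""
    idx_a = range(n)
    idx_b = range(m)
    for k in range(0, min(n, m) + 1):
        for aa in itertools.combinations(idx_a, k):
            for bb in itertools.combinations(idx_b, k):
                yield list(zip(aa, bb))


def _gap_cost(run: int, gap_open: float, gap_extend: float) -> float:
    if run <= 0:
        return 0.0
    return gap_open + (run - 1) * gap_extend


def _enumerate_scores(a, b, match, mismatch, gap_open, gap_extend, local):
    """Best score over all monotone column pairings.

    In global (overlap) mode a run at a sequence's own end is free, but
    when BOTH sequences have unaligned flanks at the same end only one of
    the runs can sit at its row's end — the other is an internal gap and
    is priced; the cheaper arrangement is taken.  In local mode all flanks
    are free.
    """
    def flank(run_a: int, run_b: int) -> float:
        if local or run_a == 0 or run_b == 0:
            return 0.0
        return max(_gap_cost(run_a, gap_open, gap_extend),
                   _gap_cost(run_b, gap_open, gap_extend))

    best = 0.0  # empty alignment
    for cols in _pairings(len(a), len(b)):
        if not cols:
            continue
        score = 0.0
        for i, j in cols:
            score += match if a[i] == b[j] else mismatch
        for (i1, j1), (i2, j2) in zip(cols, cols[1:]):
            score += _gap_cost(i2 - i1 - 1, gap_open, gap_extend)
            score += _gap_cost(j2 - j1 - 1, gap_open, gap_extend)
        score += flank(cols[0][0], cols[0][1])
        score += flank(len(a) - 1 - cols[-1][0], len(b) - 1 - cols[-1][1])
        best = max(best, score)
    return best


def best_overlap_score(a: str, b: str, match=1.0, mismatch=-2.0,
                       gap_open=-10.0, gap_extend=-1.0) -> float:
    """Optimal overlap-alignment (free end gaps) score by enumeration."""
    return _enumerate_scores(a, b, match, mismatch, gap_open, gap_extend, False)


def best_local_score(a: str, b: str, match=1.0, mismatch=-2.0,
                     gap_open=-10.0, gap_extend=-1.0) -> float:
    """Optimal local-alignment score by enumeration (all flanks free)."""
    return _enumerate_scores(a, b, match, mismatch, gap_open, gap_extend, True)


# ---------------------------------------------------------------------------
# Nussinov: maximum nested canonical pairing by exhaustive recursion.

_CANON = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def max_pairs_bruteforce(seq: str, min_loop: int = 3) -> int:
    seq = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _CANON:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


# ---------------------------------------------------------------------------
# CBC: exhaustive scan over paired columns from first principles.


def cbc_scan(seq_a: str, pairs_a, seq_b: str, pairs_b, aligned_a: str, aligned_b: str):
    """(cbc, hemi) lists computed by direct column enumeration."""
    amap = {}
    pa = pb = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            amap[pa] = pb
        if x != "-":
            pa += 1
        if y != "-":
            pb += 1
    set_b = set(pairs_b) | {(j, i) for i, j in pairs_b}
    cbc, hemi = [], []
    for i, j in pairs_a:
        if i in amap and j in amap and (amap[i], amap[j]) in set_b:
            xa, ya = seq_a[i], seq_a[j]
            xb, yb = seq_b[amap[i]], seq_b[amap[j]]
            d = (xa != xb) + (ya != yb)
            if d == 2:
                cbc.append((i, j))
            elif d == 1:
                hemi.append((i, j))
    return cbc, hemi


# ---------------------------------------------------------------------------
# PERMANOVA pseudo-F from the textbook formula, independent implementation.


def pseudo_f_direct(d, groups) -> float:
    import numpy as np
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    labels = sorted(set(groups))
    a = len(labels)
    sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in labels:
        idx = [i for i, x in enumerate(groups) if x == g]
        ng = len(idx)
        ssw += sum(
            d[i, j] ** 2 for ki, i in enumerate(idx) for j in idx[ki + 1:]
        ) / ng
    ssa = sst - ssw
    return (ssa / (a - 1)) / (ssw / (n - a))


def mantel_r_direct(d1, d2) -> float:
    import numpy as np
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n = d1.shape[0]
    v1 = [d1[i, j] for i in range(n) for j in range(i + 1, n)]
    v2 = [d2[i, j] for i in range(n) for j in range(i + 1, n)]
    v1 = np.array(v1) - np.mean(v1)
    v2 = np.array(v2) - np.mean(v2)
    return float((v1 * v2).sum() / np.sqrt((v1 ** 2).sum() * (v2 ** 2).sum()))
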