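"""ITS2 secondary structure: base-pair-maximizing folding, helix
annotation, eukaryotic hallmark validation, compensatory base changes
(CBC) and CBC-based species delimitation.

The canonical eukaryotic ITS2 structure has four helices radiating from a
basal loop, a U-U mismatch in helix II and a YGGY motif on the 5' strand
near the apex of helix III.  A CBC — both nucleotides of a conserved base
pair differing between two sequences while pairing stays canonical —
within the helix-III apex window is taken as evidence of distinct
biological species; absence of such CBCs joins two sequences into the
same species.

Folding is a deterministic built-in (Nussinov-style pair maximization with
canonical AU/GC/GU pairs and a minimum hairpin loop of 3), overridable by
user-supplied Vienna dot-bracket files; thermodynamic prediction is out of
scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .align import AlignmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "Helix",
    "ITS2Structure",
    "HallmarkReport",
    "CBCReport",
    "fold_dotbracket",
    "annotate_helices",
    "validate_hallmarks",
    "find_yggy",
    "detect_cbc",
    "delimit_species",
    "read_vienna",
    "write_vienna",
]

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def canonical_pair(x: str, y: str) -> bool:
    return (x, y) in _CANONICAL


@dataclass
class Helix:
    """A stem emanating from the basal loop.

    ``pairs`` lists (i, j) base pairs from the helix base towards the
    apex; ``apex_loop`` is the unpaired interval [start, end) enclosed by
    the innermost stem pair.
    """

    number: int  # 1-based, 5' order
    pairs: list[tuple[int, int]]
    apex_loop: tuple[int, int]

    @property
    def five_prime_span(self) -> tuple[int, int]:
        return self.pairs[0][0], self.pairs[-1][0] + 1

    @property
    def three_prime_span(self) -> tuple[int, int]:
        return self.pairs[-1][1], self.pairs[0][1] + 1


@dataclass
class ITS2Structure:
    name: str
    sequence: str  # RNA alphabet
    dotbracket: str
    helices: list[Helix] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = to_rna(self.sequence)
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError(f"{self.name}: sequence/structure length mismatch")
        self.pair_map = _pair_map(self.dotbracket)
        for i, j in self.pair_map.items():
            if i < j and not canonical_pair(self.sequence[i], self.sequence[j]):
                raise ValueError(
                    f"{self.name}: non-canonical pair {self.sequence[i]}-"
                    f"{self.sequence[j]} at ({i},{j})"
                )

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return sorted((i, j) for i, j in self.pair_map.items() if i < j)


@dataclass
class HallmarkReport:
    four_helices: bool
    helixII_UU: bool
    yggy_helixIII_5prime_apex: bool

    @property
    def overall(self) -> bool:
        return self.four_helices and self.helixII_UU and self.yggy_helixIII_5prime_apex


@dataclass
class CBCReport:
    pair: tuple[str, str]
    cbc_positions: list[tuple[tuple[int, int], tuple[int, int]]]
    hemi_cbc_positions: list[tuple[tuple[int, int], tuple[int, int]]]
    cbc_in_delimitation_window: int

    @property
    def same_species(self) -> bool:
        return self.cbc_in_delimitation_window == 0


def _pair_map(dotbracket: str) -> dict[int, int]:
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pairs


# ---------------------------------------------------------------------------
# Folding (Nussinov pair maximization)

try:  # optional acceleration for long sequences
    from numba import njit as _njit
except Exception:  # pragma: no cover - numba genuinely optional
    _njit = None


def _fill_py(can: np.ndarray, n: int) -> np.ndarray:
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j]  # i unpaired
            for k in range(i + MIN_LOOP + 1, j + 1):
                if can[i, k]:
                    left = N[i + 1, k - 1] if k - 1 > i else 0
                    right = N[k + 1, j] if k + 1 <= j else 0
                    v = 1 + left + right
                    if v > best:
                        best = v
            N[i, j] = best
    return N


if _njit is not None:
    _fill_fast = _njit(cache=True)(_fill_py)
else:  # pragma: no cover
    _fill_fast = _fill_py


def fold_dotbracket(sequence: str, min_loop: int = MIN_LOOP) -> str:
    """Deterministic base-pair-maximizing nested fold.

    Allows AU/GC/GU pairs, minimum hairpin loop ``min_loop``; the
    traceback pairs position i with the smallest qualifying j whenever
    pairing i is optimal, which fixes a unique structure among the
    maximizers.
    """
    rna = to_rna(sequence)
    if not rna:
        raise ValueError("empty sequence")
    if any(c not in "ACGU" for c in rna):
        raise ValueError("non-nucleotide characters in sequence")
    n = len(rna)
    can = np.zeros((n, n), dtype=np.bool_)
    for i in range(n):
        for j in range(i + 1, n):
            can[i, j] = canonical_pair(rna[i], rna[j])
    if min_loop == MIN_LOOP:
        N = _fill_fast(can, n)
    else:
        N = _fill_with_loop(can, n, min_loop)
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if not can[i, k]:
                continue
            left = N[i + 1, k - 1] if k - 1 > i else 0
            right = N[k + 1, j] if k + 1 <= j else 0
            if 1 + left + right == N[i, j]:
                struct[i], struct[k] = "(", ")"
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return "".join(struct)


def _fill_with_loop(can: np.ndarray, n: int, min_loop: int) -> np.ndarray:
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if can[i, k]:
                    left = N[i + 1, k - 1] if k - 1 > i else 0
                    right = N[k + 1, j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            N[i, j] = best
    return N


# ---------------------------------------------------------------------------
# Helix annotation


def _children(pair_map: dict[int, int], i: int, j: int) -> list[tuple[int, int]]:
    """Base pairs directly nested inside pair (i, j)."""
    out = []
    k = i + 1
    while k < j:
        if k in pair_map and pair_map[k] > k:
            out.append((k, pair_map[k]))
            k = pair_map[k] + 1
        else:
            k += 1
    return out


def _top_level_pairs(pair_map: dict[int, int], n: int) -> list[tuple[int, int]]:
    out = []
    k = 0
    while k < n:
        if k in pair_map and pair_map[k] > k:
            out.append((k, pair_map[k]))
            k = pair_map[k] + 1
        else:
            k += 1
    return out


def _walk_stem(pair_map: dict[int, int], root: tuple[int, int]) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Follow a stem from its basal pair to its apex.

    The stem continues through single-child pairs (bulges and internal
    loops stay inside the helix); it ends at a hairpin loop or at an
    internal multibranch, whose enclosed interval becomes the apex loop.
    """
    pairs = [root]
    cur = root
    while True:
        kids = _children(pair_map, *cur)
        if len(kids) == 1:
            cur = kids[0]
            pairs.append(cur)
        else:
            return pairs, (cur[0] + 1, cur[1])


def annotate_helices(structure: ITS2Structure) -> ITS2Structure:
    """Identify the helices branching off the basal loop.

    The basal loop is the multibranch loop closed by the outermost stem
    (descending through any unbranched outer stem), or the open exterior
    loop when the exterior level already branches.  Helices are numbered
    I..N in 5' order.
    """
    pm = structure.pair_map
    n = len(structure.sequence)
    roots = _top_level_pairs(pm, n)
    if len(roots) == 1:
        # descend the outer stem; if it ends in a multibranch, that loop is
        # basal and its branches are the helices, else the stem itself is
        # the single helix
        stem_pairs, _ = _walk_stem(pm, roots[0])
        kids = _children(pm, *stem_pairs[-1])
        if len(kids) >= 2:
            roots = kids
    helices = []
    for num, root in enumerate(roots, start=1):
        pairs, apex = _walk_stem(pm, root)
        helices.append(Helix(number=num, pairs=pairs, apex_loop=apex))
    structure.helices = helices
    return structure


# ---------------------------------------------------------------------------
# Hallmarks


def find_yggy(sequence: str) -> list[int]:
    """All start positions of the YGGY motif (Y in {C, U}), overlapping
    matches included."""
    rna = to_rna(sequence)
    return [
        i for i in range(len(rna) - 3)
        if rna[i] in "CU" and rna[i + 1] == "G" and rna[i + 2] == "G" and rna[i + 3] in "CU"
    ]


def _internal_loop_uu(seq: str, helix: Helix) -> bool:
    """True if some internal loop of the helix presents U opposite U."""
    for (i1, j1), (i2, j2) in zip(helix.pairs, helix.pairs[1:]):
        left = list(range(i1 + 1, i2))
        right = list(range(j2 + 1, j1))
        if not left or not right:
            continue  # bulge, no opposing strand
        for k in range(min(len(left), len(right))):
            if seq[left[k]] == "U" and seq[right[-1 - k]] == "U":
                return True
    return False


def helix_iii_apex_window(
    structure: ITS2Structure, apex_pairs: int = 10
) -> tuple[int, int] | None:
    """5'-strand window of helix III within ``apex_pairs`` base pairs of
    its apical loop, extended over any overlapping YGGY match.

    Returns a half-open interval on the sequence, or None if there is no
    helix III.
    """
    if len(structure.helices) < 3:
        return None
    h3 = structure.helices[2]
    stem = h3.pairs[-apex_pairs:]
    start = stem[0][0]
    end = h3.apex_loop[0]  # 5' strand runs up to the apical loop
    for m in find_yggy(structure.sequence):
        if m < end and m + 4 > start:
            start = min(start, m)
            end = max(end, m + 4)
    return start, end


def validate_hallmarks(structure: ITS2Structure, apex_pairs: int = 10) -> HallmarkReport:
    """Check the three eukaryotic ITS2 hallmarks."""
    if not structure.helices:
        annotate_helices(structure)
    seq = structure.sequence
    four = len(structure.helices) == 4
    uu = len(structure.helices) >= 2 and _internal_loop_uu(seq, structure.helices[1])
    yggy_ok = False
    win = helix_iii_apex_window(structure, apex_pairs)
    if win is not None:
        s, e = win
        yggy_ok = any(s <= m and m + 4 <= e for m in find_yggy(seq))
    return HallmarkReport(four, uu, yggy_ok)


# ---------------------------------------------------------------------------
# CBC detection and species delimitation


def _column_maps(res: AlignmentResult) -> dict[int, int]:
    """Map sequence positions of a to positions of b over aligned columns."""
    mapping: dict[int, int] = {}
    pa = pb = 0
    for x, y in zip(res.aligned_a, res.aligned_b):
        if x != "-" and y != "-":
            mapping[pa] = pb
        if x != "-":
            pa += 1
        if y != "-":
            pb += 1
    return mapping


def detect_cbc(
    a: ITS2Structure,
    b: ITS2Structure,
    alignment: AlignmentResult,
    window_a: tuple[int, int] | None = None,
    window_b: tuple[int, int] | None = None,
    apex_pairs: int = 10,
) -> CBCReport:
    """Compensatory base changes between two structures over an alignment.

    For every aligned column pair base-paired in *both* structures: a CBC
    when both nucleotides of the pair differ and both pairings are
    canonical; a hemi-CBC when exactly one differs.  The delimitation
    window defaults to the helix-III apex window of either structure
    (symmetric in a and b).
    """
    la = len(res_seq := alignment.aligned_a.replace("-", ""))
    if la != len(a.sequence) or len(alignment.aligned_b.replace("-", "")) != len(b.sequence):
        raise ValueError("alignment inconsistent with sequence lengths")
    del res_seq
    if not a.helices:
        annotate_helices(a)
    if not b.helices:
        annotate_helices(b)
    if window_a is None:
        window_a = helix_iii_apex_window(a, apex_pairs)
    if window_b is None:
        window_b = helix_iii_apex_window(b, apex_pairs)
    amap = _column_maps(alignment)
    bpairs = {(i, j) for i, j in b.pair_map.items()}
    cbc = []
    hemi = []
    n_window = 0
    for i, j in a.pairs:
        if i not in amap or j not in amap:
            continue
        bi, bj = amap[i], amap[j]
        if (bi, bj) not in bpairs:
            continue
        xa, ya = a.sequence[i], a.sequence[j]
        xb, yb = b.sequence[bi], b.sequence[bj]
        # both pairings canonical by structure invariants
        ndiff = (xa != xb) + (ya != yb)
        if ndiff == 2:
            cbc.append(((i, j), (bi, bj)))
            in_a = window_a is not None and window_a[0] <= i < window_a[1]
            in_b = window_b is not None and window_b[0] <= bi < window_b[1]
            if in_a or in_b:
                n_window += 1
        elif ndiff == 1:
            hemi.append(((i, j), (bi, bj)))
    return CBCReport(
        pair=(a.name, b.name),
        cbc_positions=cbc,
        hemi_cbc_positions=hemi,
        cbc_in_delimitation_window=n_window,
    )


def delimit_species(
    otu_ids: Sequence[str],
    structures: Mapping[str, ITS2Structure],
    align_fn,
    apex_pairs: int = 10,
) -> list[list[str]]:
    """Partition OTUs into species by absence of apex-window CBCs.

    An edge joins two OTUs when their CBC report finds no CBC in the
    helix-III apex window; species are the connected components (the
    same-species relation is closed transitively).  OTUs without a
    structure become their own species with a warning.

    ``align_fn(seq_a, seq_b) -> AlignmentResult`` supplies alignments
    (typically :func:`redsnow.align.global_align` on the RNA sequences).
    """
    g = nx.Graph()
    with_structure = []
    for oid in otu_ids:
        g.add_node(oid)
        if oid in structures:
            with_structure.append(oid)
        else:
            logger.warning("no structure for %s; left as its own species", oid)
    for i, oa in enumerate(with_structure):
        for ob in with_structure[i + 1:]:
            a, b = structures[oa], structures[ob]
            res = align_fn(a.sequence, b.sequence)
            rep = detect_cbc(a, b, res, apex_pairs=apex_pairs)
            if rep.same_species:
                g.add_edge(oa, ob)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


# ---------------------------------------------------------------------------
# Vienna I/O


def read_vienna(path: str | Path) -> list[ITS2Structure]:
    """Read Vienna dot-bracket records (>name / sequence / structure)."""
    out = []
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    k = 0
    while k < len(lines):
        if not lines[k].startswith(">"):
            raise ValueError(f"{path}: expected header at line {k + 1}")
        name = lines[k][1:].split()[0]
        seq = lines[k + 1]
        db = lines[k + 2].split()[0]
        out.append(ITS2Structure(name=name, sequence=seq, dotbracket=db))
        k += 3
    return out


def write_vienna(structures: Iterable[ITS2Structure], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f">{s.name}\n{s.sequence}\n{s.dotbracket}\n")
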