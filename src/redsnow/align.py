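"""Pairwise alignment engine with the identity/coverage conventions used
throughout the package.

Identity convention: matched columns / counted columns, where terminal-gap
columns (leading/trailing columns in which one sequence has not yet started
or has already ended) are excluded and internal gap columns count as
mismatches.  Coverage of a sequence is the fraction of its residues lying in
the non-terminal-gap core of the alignment.  Stated once here, used
everywhere (OTU clustering, reference-database construction, taxonomy).

``global_align`` is an overlap (semiglobal) alignment: end gaps are free, so
partial overlaps score naturally and coverage is informative.
``local_align`` is Smith-Waterman.  Both use affine gap scoring in which a
gap of length L costs ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

__all__ = ["AlignmentParams", "AlignmentResult", "global_align", "local_align"]


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -10.0
    gap_extend: float = -1.0


DEFAULT_PARAMS = AlignmentParams()


@dataclass
class AlignmentResult:
    """An alignment of sequences *a* and *b* plus derived statistics.

    ``alignment_length`` counts all aligned columns excluding terminal-gap
    columns for global alignments (for local alignments there are none).
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    alignment_length: int
    coverage_a: float
    coverage_b: float


def _make_aligner(params: AlignmentParams, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = params.gap_open
    al.extend_gap_score = params.gap_extend
    if mode == "global":
        al.open_end_gap_score = 0.0
        al.extend_end_gap_score = 0.0
    return al


def _aligned_strings(alignment, a: str, b: str, local: bool) -> tuple[str, str]:
    """Reconstruct gapped strings from biopython aligned blocks.

    For local mode only the aligned region is reported; for global mode the
    full sequences are laid out with end gaps.
    """
    blocks_a, blocks_b = alignment.aligned
    out_a: list[str] = []
    out_b: list[str] = []
    if len(blocks_a) == 0:
        return "", ""
    if local:
        pa, pb = blocks_a[0][0], blocks_b[0][0]
    else:
        pa, pb = 0, 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        # inter-block gaps
        out_a.append(a[pa:sa] + "-" * (sb - pb))
        out_b.append("-" * (sa - pa) + b[pb:sb])
        out_a.append(a[sa:ea])
        out_b.append(b[sb:eb])
        pa, pb = ea, eb
    if not local:
        out_a.append(a[pa:] + "-" * (len(b) - pb))
        out_b.append("-" * (len(a) - pa) + b[pb:])
    return "".join(out_a), "".join(out_b)


def _core_span(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    """Columns [start, end) excluding terminal-gap columns."""
    n = len(aligned_a)
    start = 0
    while start < n and ("-" in (aligned_a[start], aligned_b[start])):
        start += 1
    end = n
    while end > start and ("-" in (aligned_a[end - 1], aligned_b[end - 1])):
        end -= 1
    return start, end


def _result_from_strings(aligned_a: str, aligned_b: str, score: float,
                         len_a: int, len_b: int, local: bool) -> AlignmentResult:
    if local:
        start, end = 0, len(aligned_a)
    else:
        start, end = _core_span(aligned_a, aligned_b)
    core_a = aligned_a[start:end]
    core_b = aligned_b[start:end]
    ncols = end - start
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    identity = matches / ncols if ncols else 0.0
    res_a = sum(1 for x in core_a if x != "-")
    res_b = sum(1 for x in core_b if x != "-")
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identity=identity,
        alignment_length=ncols,
        coverage_a=res_a / len_a if len_a else 0.0,
        coverage_b=res_b / len_b if len_b else 0.0,
    )


def global_align(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> AlignmentResult:
    """Optimal overlap alignment (free end gaps, affine internal gaps)."""
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    aligner = _make_aligner(params, "global")
    aln = aligner.align(a, b)[0]
    sa, sb = _aligned_strings(aln, a, b, local=False)
    return _result_from_strings(sa, sb, aln.score, len(a), len(b), local=False)


def local_align(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> AlignmentResult:
    """Optimal local (Smith-Waterman) alignment under affine gaps."""
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _make_aligner(params, "local")
    alns = aligner.align(a, b)
    if alns.score <= 0:
        return AlignmentResult("", "", 0.0, 0.0, 0, 0.0, 0.0)
    aln = alns[0]
    sa, sb = _aligned_strings(aln, a, b, local=True)
    return _result_from_strings(sa, sb, aln.score, len(a), len(b), local=True)


def identity(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Overlap-alignment identity between two sequences."""
    return global_align(a, b, params).identity


def edlib_align(a: str, b: str) -> AlignmentResult:
    """Fast unit-cost (edit-distance) global alignment.

    Statistics follow the same conventions as :func:`global_align` but the
    alignment minimizes edits rather than maximizing the affine-gap score;
    for near-identical sequences the two coincide.  Used where throughput
    matters more than affine optimality (e.g. all-pairs CBC scans).
    """
    import edlib as _edlib

    if not a or not b:
        raise ValueError("edlib_align requires non-empty sequences")
    res = _edlib.align(a, b, mode="NW", task="path")
    nice = _edlib.getNiceAlignment(res, a, b)
    sa, sb = nice["query_aligned"], nice["target_aligned"]
    return _result_from_strings(sa, sb, -res["editDistance"], len(a), len(b), local=False)
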