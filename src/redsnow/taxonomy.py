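"""Alignment-based taxonomic assignment against a labelled reference set,
and construction of an in-house reference database from long Sanger-style
18S-ITS2 sequences.

Assignment gates follow homology-search practice for these markers: a
query is assigned to its top-scoring reference only when E-value < 1e-8,
identity > 90% and alignment length > 200 bp (ITS2) or > 150 bp (18S).
Queries failing the gates — or assigned to no algal group — are flagged
for downstream exclusion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .align import AlignmentParams, DEFAULT_PARAMS, local_align
from .clustering import furthest_neighbour_cluster
from .reads import IUPAC

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceRecord",
    "TaxonAssignment",
    "evalue",
    "assign_taxonomy",
    "build_reference_db",
    "read_reference_db",
    "write_reference_db",
]

# Karlin-Altschul ungapped nucleotide constants for +1/-2 scoring
LAMBDA = 1.28
K = 0.46

ALEN_GATE = {"ITS2": 200, "18S": 150}
EVALUE_GATE = 1e-8
IDENTITY_GATE = 0.90


@dataclass(frozen=True)
class ReferenceRecord:
    ref_id: str
    sequence: str
    marker: str  # ITS2 | 18S
    group_label: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.ref_id}: empty sequence")
        if not self.group_label:
            raise ValueError(f"{self.ref_id}: empty group label")


@dataclass
class TaxonAssignment:
    query_id: str
    best_ref: str | None
    evalue: float
    identity: float
    alignment_length: int
    assigned: bool
    group_label: str = "unassigned"


def evalue(score: float, query_len: int, db_len: int,
           lam: float = LAMBDA, k: float = K) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be positive")
    return k * query_len * db_len * math.exp(-lam * score)


def assign_taxonomy(
    query_id: str,
    query: str,
    db: Sequence[ReferenceRecord],
    marker: str = "ITS2",
    params: AlignmentParams = DEFAULT_PARAMS,
) -> TaxonAssignment:
    """Assign a query to the top-scoring reference if it passes the gates.

    Ties on score are broken by lowest E-value (equal here, since E is a
    function of score and lengths) and then lexicographic ref_id.
    """
    if not db:
        raise ValueError("empty reference database")
    if marker not in ALEN_GATE:
        raise ValueError(f"unknown marker {marker!r}")
    db_len = sum(len(r.sequence) for r in db)
    best: tuple[float, str] | None = None
    best_res = None
    best_rec = None
    for rec in sorted(db, key=lambda r: r.ref_id):
        res = local_align(query, rec.sequence, params)
        key = (-res.score, rec.ref_id)
        if best is None or key < best:
            best = key
            best_res = res
            best_rec = rec
    e = evalue(best_res.score, len(query), db_len)
    assigned = (
        e < EVALUE_GATE
        and best_res.identity > IDENTITY_GATE
        and best_res.alignment_length > ALEN_GATE[marker]
    )
    return TaxonAssignment(
        query_id=query_id,
        best_ref=best_rec.ref_id,
        evalue=e,
        identity=best_res.identity,
        alignment_length=best_res.alignment_length,
        assigned=assigned,
        group_label=best_rec.group_label if assigned else "unassigned",
    )


def _find_motif(seq: str, motif: str) -> int:
    """First IUPAC-aware occurrence of motif in seq, or -1."""
    k = len(motif)
    for i in range(len(seq) - k + 1):
        if all(b in IUPAC.get(p.upper(), "") for p, b in zip(motif, seq[i:i + k])):
            return i
    return -1


def extract_its2(seq: str, motif_5p: str, motif_3p: str) -> str | None:
    """ITS2 interval between user-supplied flanking motifs (exclusive of
    the motifs themselves); None when either motif is absent."""
    i = _find_motif(seq, motif_5p)
    if i < 0:
        return None
    start = i + len(motif_5p)
    j = _find_motif(seq[start:], motif_3p)
    if j < 0:
        return None
    return seq[start:start + j]


def build_reference_db(
    long_reads: Mapping[str, str],
    sample_of: Mapping[str, str],
    group_of: Mapping[str, str],
    flanking_motifs: tuple[str, str] | None = None,
    id_threshold: float = 0.99,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[ReferenceRecord]:
    """Build an in-house ITS2 reference set from long 18S-ITS2 sequences.

    ITS2 intervals are cut out by flanking motifs (the full sequence is
    used when no motifs are given), clustered per sample with the furthest
    neighbour algorithm at 99% identity, and one representative per
    cluster (longest sequence, ties lexicographic by id) is emitted with
    its group label.
    """
    its2: dict[str, str] = {}
    for rid, seq in long_reads.items():
        if flanking_motifs is not None:
            cut = extract_its2(seq, *flanking_motifs)
            if cut is None or not cut:
                logger.warning("flanking motifs not found in %s; skipped", rid)
                continue
            its2[rid] = cut
        else:
            its2[rid] = seq
    refs: list[ReferenceRecord] = []
    samples = sorted({sample_of[r] for r in its2})
    for sample in samples:
        members = {r: its2[r] for r in its2 if sample_of[r] == sample}
        for cluster in furthest_neighbour_cluster(members, id_threshold, params):
            # longest; ties -> lexicographically smallest id
            longest = max(len(members[r]) for r in cluster)
            rep = sorted(r for r in cluster if len(members[r]) == longest)[0]
            refs.append(ReferenceRecord(
                ref_id=rep, sequence=members[rep], marker="ITS2",
                group_label=group_of[rep],
            ))
    return refs


def write_reference_db(refs: Sequence[ReferenceRecord], fasta: str | Path, labels: str | Path) -> None:
    with open(fasta, "w") as fh:
        for r in refs:
            fh.write(f">{r.ref_id}\n{r.sequence}\n")
    with open(labels, "w") as fh:
        fh.write("ref_id\tmarker\tgroup_label\n")
        for r in refs:
            fh.write(f"{r.ref_id}\t{r.marker}\t{r.group_label}\n")


def read_reference_db(fasta: str | Path, labels: str | Path) -> list[ReferenceRecord]:
    seqs: dict[str, str] = {}
    rid = None
    for line in Path(fasta).read_text().splitlines():
        line = line.strip()
        if line.startswith(">"):
            rid = line[1:].split()[0]
            seqs[rid] = ""
        elif rid:
            seqs[rid] += line
    out = []
    lines = Path(labels).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        rid, marker, label = line.split("\t")
        out.append(ReferenceRecord(rid, seqs[rid], marker, label))
    return out
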