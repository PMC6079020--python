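"""Raw-read processing: demultiplexing, quality truncation, pair merging,
quality filtering, primer trimming and exact dereplication into phylotypes.

The processing order mirrors a standard dual-indexed MiSeq amplicon run:
pairs are assigned to samples by exact dual-index match, 3' ends are
truncated at the first low-quality base, mates are merged over their best
ungapped overlap, merged reads are filtered (ambiguous bases, minimum
length, contaminant screen), primers are trimmed, and the surviving reads
are collapsed into abundance-annotated unique sequences ("phylotypes").
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRead",
    "SampleMetadata",
    "Phylotype",
    "QCLedger",
    "read_fastq",
    "read_metadata",
    "demultiplex",
    "truncate_at_low_quality",
    "merge_read_pair",
    "quality_filter",
    "trim_primer",
    "dereplicate",
    "remove_singletons",
    "write_phylotypes",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ACGT_SET = frozenset("ACGT")

# IUPAC nucleotide ambiguity codes -> the set of bases each matches
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRead:
    id: str
    bases: str
    quals: Sequence[int]
    mate: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"{self.id}: bases and quals differ in length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    site: str
    region: str
    latitude: float
    longitude: float
    index_pair: tuple[str, str]  # (i7, i5)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.sample_id}: latitude out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.sample_id}: longitude out of range")


@dataclass
class Phylotype:
    phylotype_id: str
    sequence: str
    per_sample_counts: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.per_sample_counts.values())


@dataclass
class QCLedger:
    """Per-stage read accounting; reads in == reads out + discards at
    every stage."""

    counts: dict[str, int] = field(default_factory=lambda: defaultdict(int))

    def add(self, key: str, n: int = 1) -> None:
        self.counts[key] += n

    def __getitem__(self, key: str) -> int:
        return self.counts.get(key, 0)

    def check_conservation(self, stage_in: str, outs: Iterable[str]) -> None:
        total_out = sum(self[k] for k in outs)
        if self[stage_in] != total_out:
            raise AssertionError(
                f"ledger conservation violated: {stage_in}={self[stage_in]} "
                f"!= sum({list(outs)})={total_out}"
            )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            for k in sorted(self.counts):
                fh.write(f"{k}\t{self.counts[k]}\n")


# ---------------------------------------------------------------------------
# I/O

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path, mate: str = "forward") -> Iterator[SequenceRead]:
    """Stream a FASTQ file (Sanger Phred+33), plain or gzipped."""
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield SequenceRead(
                id=title,
                bases=seq.upper(),
                quals=np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33,
                mate=mate,
            )


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(min(q, 93) + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{q}\n")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Sample metadata TSV: sample_id, site, region, lat, lon, i7, i5."""
    samples: list[SampleMetadata] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            samples.append(SampleMetadata(
                sample_id=f[idx["sample_id"]],
                site=f[idx["site"]],
                region=f[idx["region"]],
                latitude=float(f[idx["lat"]]),
                longitude=float(f[idx["lon"]]),
                index_pair=(f[idx["i7"]], f[idx["i5"]]),
            ))
    return samples


def write_metadata(samples: Iterable[SampleMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsite\tregion\tlat\tlon\ti7\ti5\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.site}\t{s.region}\t{s.latitude}\t"
                     f"{s.longitude}\t{s.index_pair[0]}\t{s.index_pair[1]}\n")


def index_pair_from_header(header: str) -> tuple[str, str] | None:
    """Extract the dual index from an Illumina-style header comment
    ``... 1:N:0:I7+I5``."""
    parts = header.split()
    if len(parts) < 2:
        return None
    fields = parts[-1].split(":")
    if len(fields) < 4 or "+" not in fields[3]:
        return None
    i7, _, i5 = fields[3].partition("+")
    return i7, i5


# ---------------------------------------------------------------------------
# Operations

def demultiplex(
    read_pairs: Iterable[tuple[SequenceRead, SequenceRead]],
    samples: Sequence[SampleMetadata],
    ledger: QCLedger | None = None,
) -> dict[str, list[tuple[SequenceRead, SequenceRead]]]:
    """Assign read pairs to samples by *exact* dual-index match.

    Pairs whose index pair does not exactly equal any declared sample's
    index pair are discarded (no error correction).
    """
    pairs_seen = Counter(s.index_pair for s in samples)
    dup = [p for p, n in pairs_seen.items() if n > 1]
    if dup:
        raise ValueError(f"duplicate index pairs in metadata: {dup}")
    by_index = {s.index_pair: s.sample_id for s in samples}
    out: dict[str, list[tuple[SequenceRead, SequenceRead]]] = {
        s.sample_id: [] for s in samples
    }
    ledger = ledger if ledger is not None else QCLedger()
    for fwd, rev in read_pairs:
        ledger.add("demux_in")
        ip = index_pair_from_header(fwd.id)
        sample = by_index.get(ip) if ip is not None else None
        if sample is None:
            ledger.add("demux_discarded_index")
        else:
            out[sample].append((fwd, rev))
            ledger.add("demux_assigned")
            ledger.add(f"assigned_{sample}")
    ledger.check_conservation("demux_in", ["demux_assigned", "demux_discarded_index"])
    return out


def truncate_at_low_quality(read: SequenceRead, qmin: int = 3) -> SequenceRead:
    """Truncate immediately before the first base with quality < qmin
    (USEARCH fastq_truncqual semantics)."""
    if qmin < 0:
        raise ValueError("qmin must be >= 0")
    q = np.asarray(read.quals)
    bad = np.flatnonzero(q < qmin)
    cut = int(bad[0]) if bad.size else len(read)
    return SequenceRead(read.id, read.bases[:cut], q[:cut], read.mate)


def merge_read_pair(
    fwd: SequenceRead,
    rev: SequenceRead,
    min_overlap: int = 16,
    max_mismatch_frac: float = 0.25,
) -> SequenceRead | None:
    """Merge a pair over its best ungapped overlap.

    The reverse read is reverse-complemented; all overlap lengths
    ``min_overlap <= o <= min(len(fwd), len(rev))`` are scored and the
    overlap maximizing the number of matching positions (ties: longer
    overlap) is taken, provided its mismatch fraction is at most
    ``max_mismatch_frac``.  At overlap mismatches the higher-quality base
    wins (tie: forward base); the consensus quality is the max of the two.
    Returns None on failure.
    """
    r = revcomp(rev.bases)
    rq = np.asarray(rev.quals)[::-1]
    la, lb = len(fwd), len(rev)
    best: tuple[int, int, int] | None = None  # (matches, overlap, mismatches)
    for o in range(min_overlap, min(la, lb) + 1):
        fa = fwd.bases[la - o:]
        rb = r[:o]
        mism = sum(1 for x, y in zip(fa, rb) if x != y)
        if mism / o > max_mismatch_frac:
            continue
        matches = o - mism
        if best is None or (matches, o) > (best[0], best[1]):
            best = (matches, o, mism)
    if best is None:
        return None
    o = best[1]
    bases = list(fwd.bases[: la - o])
    quals = list(fwd.quals[: la - o])
    for k in range(o):
        fb, fq = fwd.bases[la - o + k], fwd.quals[la - o + k]
        rb, rqk = r[k], rq[k]
        if fb == rb:
            bases.append(fb)
        else:
            bases.append(rb if rqk > fq else fb)
        quals.append(max(fq, rqk))
    bases.extend(r[o:])
    quals.extend(rq[o:])
    return SequenceRead(fwd.id, "".join(bases), quals, "forward")


def merge_pairs_batch(
    pairs: Sequence[tuple[SequenceRead, SequenceRead]],
    min_overlap: int = 16,
    max_mismatch_frac: float = 0.25,
    ledger: QCLedger | None = None,
) -> list[SequenceRead]:
    """Vectorized pair merging for large same-length batches.

    Groups pairs by mate lengths and scans candidate overlaps with numpy;
    semantics identical to :func:`merge_read_pair`.
    """
    ledger = ledger if ledger is not None else QCLedger()
    merged: list[SequenceRead] = []
    groups: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i, (f, r) in enumerate(pairs):
        groups[(len(f), len(r))].append(i)
    out: dict[int, SequenceRead | None] = {}
    for (la, lb), idxs in groups.items():
        if min(la, lb) < min_overlap or la == 0 or lb == 0:
            for i in idxs:
                out[i] = None
            continue
        F = np.frombuffer(
            "".join(pairs[i][0].bases for i in idxs).encode(), dtype=np.uint8
        ).reshape(len(idxs), la)
        R = np.frombuffer(
            "".join(revcomp(pairs[i][1].bases) for i in idxs).encode(), dtype=np.uint8
        ).reshape(len(idxs), lb)
        FQ = np.stack([np.asarray(pairs[i][0].quals) for i in idxs])
        RQ = np.stack([np.asarray(pairs[i][1].quals)[::-1] for i in idxs])
        n = len(idxs)
        best_matches = np.full(n, -1, dtype=np.int64)
        best_o = np.zeros(n, dtype=np.int64)
        for o in range(min_overlap, min(la, lb) + 1):
            mism = np.count_nonzero(F[:, la - o:] != R[:, :o], axis=1)
            ok = mism <= max_mismatch_frac * o
            matches = o - mism
            # maximize matches, ties -> longer overlap (o increases)
            better = ok & (matches >= best_matches)
            best_o[better] = o
            best_matches[better] = matches[better]
        for o in np.unique(best_o[best_matches >= 0]):
            o = int(o)
            rows = np.flatnonzero((best_o == o) & (best_matches >= 0))
            fo = F[rows, la - o:]
            ro = R[rows, :o]
            fq = FQ[rows, la - o:]
            rq = RQ[rows, :o]
            cons = np.where((fo == ro) | (rq <= fq), fo, ro)
            consq = np.maximum(fq, rq)
            merged_b = np.concatenate([F[rows, : la - o], cons, R[rows, o:]], axis=1)
            merged_q = np.concatenate([FQ[rows, : la - o], consq, RQ[rows, o:]], axis=1)
            for r_i, row in enumerate(rows):
                i = idxs[row]
                out[i] = SequenceRead(
                    pairs[i][0].id,
                    merged_b[r_i].tobytes().decode(),
                    merged_q[r_i],
                    "forward",
                )
        for row in np.flatnonzero(best_matches < 0):
            out[idxs[row]] = None
    for i in range(len(pairs)):
        m = out[i]
        ledger.add("merge_in")
        if m is None:
            ledger.add("merge_failed")
        else:
            ledger.add("merged")
            merged.append(m)
    ledger.check_conservation("merge_in", ["merged", "merge_failed"])
    return merged


def quality_filter(
    read: SequenceRead,
    min_len: int = 50,
    contaminants: Mapping[str, str] | None = None,
    contaminant_min_span: int = 60,
    contaminant_min_identity: float = 0.90,
) -> tuple[bool, str | None]:
    """Keep/discard decision with a reason.

    Discards reads containing non-ACGT bases, reads shorter than
    ``min_len`` (strictly), and reads whose local alignment to any
    contaminant reference covers >= ``contaminant_min_span`` nt at
    >= ``contaminant_min_identity`` identity.
    """
    if not _ACGT_SET.issuperset(read.bases):
        return False, "ambiguous"
    if len(read) < min_len:
        return False, "short"
    if contaminants:
        from .align import local_align
        for ref in contaminants.values():
            res = local_align(read.bases, ref)
            if (res.alignment_length >= contaminant_min_span
                    and res.identity >= contaminant_min_identity):
                return False, "contaminant"
    return True, None


def iupac_mismatches(primer: str, window: str) -> int:
    """Mismatch count of an IUPAC primer against a same-length window."""
    return sum(
        1 for p, b in zip(primer, window)
        if b not in IUPAC.get(p.upper(), "")
    )


def trim_primer(
    read: SequenceRead,
    primer: str,
    max_mismatches: int = 4,
    end: str = "5prime",
) -> SequenceRead | None:
    """Remove a primer match from the 5' (or 3') end of a read.

    The primer may contain IUPAC ambiguity codes; a code matches any base
    in its set.  Returns the trimmed read, or None when the primer does not
    match within ``max_mismatches`` (no-trim).
    For ``end='3prime'`` the primer is searched as its reverse complement
    at the 3' end (merged-read convention for the reverse primer).
    """
    if not primer:
        raise ValueError("empty primer")
    k = len(primer)
    if len(read) < k:
        return None
    if end == "5prime":
        if iupac_mismatches(primer, read.bases[:k]) <= max_mismatches:
            return SequenceRead(read.id, read.bases[k:], list(read.quals[k:]), read.mate)
        return None
    if end == "3prime":
        rc = revcomp_iupac(primer)
        if iupac_mismatches(rc, read.bases[-k:]) <= max_mismatches:
            return SequenceRead(read.id, read.bases[:-k], list(read.quals[:-k]), read.mate)
        return None
    raise ValueError(f"unknown end: {end}")


_IUPAC_COMP = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def revcomp_iupac(seq: str) -> str:
    return seq.upper().translate(_IUPAC_COMP)[::-1]


def dereplicate(reads: Mapping[str, Sequence[str]]) -> list[Phylotype]:
    """Collapse identical sequences into phylotypes with per-sample counts.

    Output is sorted by total count descending, ties broken by sequence
    lexicographic order, and ids are assigned in that order (P000001, ...).
    """
    per_seq: dict[str, Counter] = defaultdict(Counter)
    for sample_id, seqs in reads.items():
        for s in seqs:
            per_seq[s][sample_id] += 1
    ordered = sorted(
        per_seq.items(), key=lambda kv: (-sum(kv[1].values()), kv[0])
    )
    return [
        Phylotype(f"P{i + 1:06d}", seq, dict(counts))
        for i, (seq, counts) in enumerate(ordered)
    ]


def remove_singletons(
    phylotypes: Sequence[Phylotype], ledger: QCLedger | None = None
) -> list[Phylotype]:
    """Drop phylotypes consisting of a single read."""
    ledger = ledger if ledger is not None else QCLedger()
    kept = []
    for p in phylotypes:
        if p.total_count == 1:
            ledger.add("singletons_removed")
        else:
            kept.append(p)
    return kept


def write_phylotypes(
    phylotypes: Sequence[Phylotype], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    """FASTA with USEARCH-style ';size=N' annotations + per-sample TSV."""
    with open(fasta_path, "w") as fh:
        for p in phylotypes:
            fh.write(f">{p.phylotype_id};size={p.total_count}\n{p.sequence}\n")
    with open(tsv_path, "w") as fh:
        fh.write("phylotype_id\tsample_id\tcount\n")
        for p in phylotypes:
            for sample_id in sorted(p.per_sample_counts):
                fh.write(f"{p.phylotype_id}\t{sample_id}\t{p.per_sample_counts[sample_id]}\n")


def read_phylotypes(fasta_path: str | Path, tsv_path: str | Path) -> list[Phylotype]:
    seqs: dict[str, str] = {}
    with open(fasta_path) as fh:
        pid = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                pid = line[1:].split(";")[0]
                seqs[pid] = ""
            elif pid:
                seqs[pid] += line
    counts: dict[str, dict[str, int]] = defaultdict(dict)
    with open(tsv_path) as fh:
        next(fh)
        for line in fh:
            pid, sid, c = line.rstrip("\n").split("\t")
            counts[pid][sid] = int(c)
    return [Phylotype(pid, seq, counts.get(pid, {})) for pid, seq in seqs.items()]
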