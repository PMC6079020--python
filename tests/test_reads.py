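"""Read processing: demultiplexing, truncation, merging, QC, primers,
dereplication."""

import numpy as np
import pytest

from redsnow.reads import (
    Phylotype, QCLedger, SampleMetadata, SequenceRead, demultiplex,
    dereplicate, merge_pairs_batch, merge_read_pair, quality_filter,
    remove_singletons, revcomp, trim_primer, truncate_at_low_quality,
)


def read(bases, quals=None, rid="r", mate="forward"):
    if quals is None:
        quals = [35] * len(bases)
    return SequenceRead(rid, bases, quals, mate)


def sample(sid, i7, i5, region="Svalbard"):
    return SampleMetadata(sid, f"site_{sid}", region, 78.0, 12.0, (i7, i5))


class TestDemultiplex:
    def pair(self, i7, i5):
        hdr = f"x 1:N:0:{i7}+{i5}"
        return (read("ACGT", rid=hdr), read("ACGT", rid=hdr, mate="reverse"))

    def test_exact_index_match_assigns(self):
        s1 = sample("S1", "AAAAAAAA", "CCCCCCCC")
        out = demultiplex([self.pair("AAAAAAAA", "CCCCCCCC")], [s1])
        assert len(out["S1"]) == 1

    def test_single_mismatch_is_discarded(self):
        s1 = sample("S1", "AAAAAAAA", "CCCCCCCC")
        led = QCLedger()
        out = demultiplex([self.pair("AAAAAAAT", "CCCCCCCC")], [s1], led)
        assert out["S1"] == []
        assert led["demux_discarded_index"] == 1

    def test_empty_stream(self):
        led = QCLedger()
        out = demultiplex([], [sample("S1", "A" * 8, "C" * 8)], led)
        assert out == {"S1": []}
        assert led["demux_in"] == 0

    def test_duplicate_index_pairs_rejected(self):
        s1 = sample("S1", "A" * 8, "C" * 8)
        s2 = sample("S2", "A" * 8, "C" * 8)
        with pytest.raises(ValueError):
            demultiplex([], [s1, s2])


class TestTruncate:
    def test_all_above_threshold_is_noop(self):
        r = read("ACGT", [30, 30, 30, 30])
        assert truncate_at_low_quality(r, 3).bases == "ACGT"

    def test_first_base_low_gives_empty(self):
        r = read("ACGT", [2, 30, 30, 30])
        assert len(truncate_at_low_quality(r, 3)) == 0

    def test_truncates_before_first_low_base(self):
        r = read("ACGT", [30, 30, 2, 30])
        assert truncate_at_low_quality(r, 3).bases == "AC"


class TestMerge:
    def test_perfect_overlap_length(self):
        # fwd 10 nt, rev 10 nt, 6-nt perfect overlap -> 14-nt merged read
        amplicon = "AACCGGTTACGTGA"
        fwd = read(amplicon[:10])
        rev = read(revcomp(amplicon[4:]), mate="reverse")
        m = merge_read_pair(fwd, rev, min_overlap=6)
        assert m is not None and m.bases == amplicon

    def test_no_sufficient_overlap_fails(self):
        m = merge_read_pair(read("AAAACCCC"), read("GTGTGTGT", mate="reverse"),
                            min_overlap=6, max_mismatch_frac=0.0)
        assert m is None

    def test_higher_quality_base_wins_at_mismatch(self):
        # 2-base overlap toy: fwd ends ...TA (Q40), rev disagrees with G (Q10)
        fwd = read("CCTA", [40, 40, 40, 40])
        rev = read(revcomp("GA"), [10, 10], mate="reverse")
        m = merge_read_pair(fwd, rev, min_overlap=2, max_mismatch_frac=0.5)
        assert m.bases == "CCTA"
        # now give the reverse read the higher quality
        rev_hi = read(revcomp("GA"), [44, 44], mate="reverse")
        m2 = merge_read_pair(fwd, rev_hi, min_overlap=2, max_mismatch_frac=0.5)
        assert m2.bases == "CCGA"
        assert list(m2.quals[-2:]) == [44, 44]

    def test_merge_symmetry_on_perfect_overlaps(self, rng):
        from conftest import random_seq
        for _ in range(20):
            amplicon = random_seq(rng, 40)
            fwd = read(amplicon[:28])
            rev = read(revcomp(amplicon[12:]), mate="reverse")
            m1 = merge_read_pair(fwd, rev, min_overlap=10)
            # swap roles: rev-as-fwd, fwd-as-rev
            m2 = merge_read_pair(
                read(revcomp(amplicon[12:])),
                read(amplicon[:28], mate="reverse"),
                min_overlap=10,
            )
            assert m1.bases == revcomp(m2.bases) == amplicon

    def test_batch_matches_scalar(self, rng):
        from conftest import random_seq, mutate_at
        pairs = []
        for _ in range(30):
            amplicon = random_seq(rng, 60)
            fwd = read(amplicon[:40])
            rseq = revcomp(amplicon[20:])
            if rng.random() < 0.5:  # plant a disagreement in the overlap
                rseq = mutate_at(rseq, [int(rng.integers(0, 20))], rng)
            rev = read(rseq, list(rng.integers(20, 41, size=40)), mate="reverse")
            pairs.append((fwd, rev))
        batch = merge_pairs_batch(pairs, min_overlap=10)
        scalar = [merge_read_pair(f, r, min_overlap=10) for f, r in pairs]
        scalar = [s for s in scalar if s is not None]
        assert [m.bases for m in batch] == [s.bases for s in scalar]


class TestQualityFilter:
    def test_ambiguous_base_discarded(self):
        keep, reason = quality_filter(read("ACGNT" + "A" * 60))
        assert not keep and reason == "ambiguous"

    def test_length_boundary_is_strict(self):
        assert quality_filter(read("A" * 49))[1] == "short"
        assert quality_filter(read("A" * 50))[0]

    def test_contaminant_screen(self, rng):
        from conftest import random_seq
        contaminant = random_seq(rng, 400)
        r = read(contaminant[100:300])  # 200-nt exact substring
        keep, reason = quality_filter(r, contaminants={"phix": contaminant})
        assert not keep and reason == "contaminant"
        clean = read(random_seq(rng, 200))
        assert quality_filter(clean, contaminants={"phix": contaminant})[0]


class TestTrimPrimer:
    PRIMER = "CCAGCASCYGCGGTAATTCC"  # S and Y are IUPAC codes

    def test_exact_primer_removed(self):
        r = read("CCAGCACCCGCGGTAATTCC" + "AAAA")  # S->C, Y->C resolved
        t = trim_primer(r, self.PRIMER, max_mismatches=4)
        assert t.bases == "AAAA"

    def test_mismatch_boundary_four_vs_five(self):
        body = "GGGG"
        # resolved primer CCAGCACCCGCGGTAATTCC mutated at positions 0-3 / 0-4
        four = "GGGTCACCCGCGGTAATTCC" + body
        r4 = trim_primer(read(four), self.PRIMER, max_mismatches=4)
        assert r4 is not None and r4.bases == body
        five = "GGGTAACCCGCGGTAATTCC" + body
        assert trim_primer(read(five), self.PRIMER, max_mismatches=4) is None

    def test_iupac_code_matches_its_set(self):
        # primer base S matches G
        r = read("CCAGCAGCCGCGGTAATTCC" + "TT")
        assert trim_primer(r, self.PRIMER, max_mismatches=0).bases == "TT"

    def test_empty_primer_rejected(self):
        with pytest.raises(ValueError):
            trim_primer(read("ACGT"), "")

    def test_three_prime_reverse_complement_trim(self):
        r = read("AAAA" + revcomp("TCCTCCGC"))
        t = trim_primer(r, "TCCTCCGC", max_mismatches=0, end="3prime")
        assert t.bases == "AAAA"


class TestDereplicate:
    def test_counts_and_order(self):
        out = dereplicate({"S1": ["X" * 60] * 3, "S2": ["Y" * 60]})
        assert [(p.sequence[0], p.total_count) for p in out] == [("X", 3), ("Y", 1)]

    def test_same_sequence_across_samples_is_one_phylotype(self):
        out = dereplicate({"S1": ["ACGT"], "S2": ["ACGT", "ACGT"]})
        assert len(out) == 1
        assert out[0].per_sample_counts == {"S1": 1, "S2": 2}

    def test_empty_input(self):
        assert dereplicate({}) == []

    def test_roundtrip_idempotent(self, rng):
        from conftest import random_seq
        seqs = [random_seq(rng, 30) for _ in range(6)]
        reads = {"A": [seqs[i] for i in rng.integers(0, 6, 40)],
                 "B": [seqs[i] for i in rng.integers(0, 6, 40)]}
        once = dereplicate(reads)
        expanded = {
            sid: [p.sequence for p in once for _ in range(p.per_sample_counts.get(sid, 0))]
            for sid in reads
        }
        twice = dereplicate(expanded)
        assert [(p.sequence, p.per_sample_counts) for p in once] == \
               [(p.sequence, p.per_sample_counts) for p in twice]


class TestSingletons:
    def test_removes_only_singletons(self):
        ps = [Phylotype("a", "A", {"s": 3}), Phylotype("b", "C", {"s": 1})]
        assert [p.phylotype_id for p in remove_singletons(ps)] == ["a"]

    def test_count_two_kept(self):
        ps = [Phylotype("a", "A", {"s": 2})]
        assert remove_singletons(ps) == ps

    def test_all_singletons(self):
        ps = [Phylotype(str(i), "ACGT", {"s": 1}) for i in range(3)]
        assert remove_singletons(ps) == []


def test_ledger_conservation_check():
    led = QCLedger()
    led.add("in", 5)
    led.add("out", 3)
    led.add("bad", 2)
    led.check_conservation("in", ["out", "bad"])
    led.add("bad", 1)
    with pytest.raises(AssertionError):
        led.check_conservation("in", ["out", "bad"])
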