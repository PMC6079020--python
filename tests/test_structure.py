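"""Folding, helix annotation, hallmark validation, CBC detection and
species delimitation."""

import pytest

import _oracles
from conftest import random_seq
from redsnow.align import global_align
from redsnow.sim import make_scaffold
from redsnow.structure import (
    ITS2Structure, annotate_helices, delimit_species, detect_cbc, find_yggy,
    fold_dotbracket, helix_iii_apex_window, read_vienna, to_rna,
    validate_hallmarks, write_vienna,
)


class TestFolding:
    def test_unpairable_sequence(self):
        assert fold_dotbracket("AAAA") == "...."

    def test_simple_hairpin(self):
        assert fold_dotbracket("GGGAAACCC") == "(((...)))"

    def test_nonnucleotide_rejected(self):
        with pytest.raises(ValueError):
            fold_dotbracket("ACGX")
        with pytest.raises(ValueError):
            fold_dotbracket("")

    def test_pair_count_matches_bruteforce(self, rng):
        """DP pair count equals the exhaustive-search maximum for random
        short sequences."""
        for _ in range(200):
            s = random_seq(rng, int(rng.integers(1, 13)), alphabet="ACGU")
            db = fold_dotbracket(s)
            assert db.count("(") == _oracles.max_pairs_bruteforce(s), s


class TestHelices:
    def test_single_hairpin_is_one_helix(self):
        s = ITS2Structure("x", "GGAAACC", "((...))")
        annotate_helices(s)
        assert len(s.helices) == 1
        assert s.helices[0].apex_loop == (2, 5)

    def test_two_exterior_branches(self):
        s = ITS2Structure("x", "GGAAACCAAGGAAACC", "((...))..((...))")
        annotate_helices(s)
        assert len(s.helices) == 2
        assert s.helices[0].pairs[0][0] < s.helices[1].pairs[0][0]

    def test_scaffold_has_four_helices(self):
        sc = make_scaffold()
        s = annotate_helices(sc.structure("scaffold"))
        assert [h.number for h in s.helices] == [1, 2, 3, 4]


class TestHallmarks:
    def test_canonical_scaffold_passes_all(self):
        sc = make_scaffold()
        rep = validate_hallmarks(annotate_helices(sc.structure("s")))
        assert rep.four_helices and rep.helixII_UU and rep.yggy_helixIII_5prime_apex
        assert rep.overall

    def test_deleting_helix_iv_fails_only_four_helices(self):
        sc = make_scaffold()
        s = annotate_helices(sc.structure("s"))
        h4 = s.helices[3]
        db = list(sc.dotbracket)
        for i, j in h4.pairs:
            db[i] = db[j] = "."
        mutant = annotate_helices(ITS2Structure("m", sc.sequence, "".join(db)))
        rep = validate_hallmarks(mutant)
        assert not rep.four_helices
        assert rep.helixII_UU and rep.yggy_helixIII_5prime_apex
        assert not rep.overall

    def test_removing_uu_mismatch_fails_only_that_check(self):
        sc = make_scaffold()
        s = annotate_helices(sc.structure("s"))
        h2 = s.helices[1]
        # locate the 1x1 internal loop of helix II and mutate one U
        seq = list(sc.sequence)
        found = False
        for (i1, j1), (i2, j2) in zip(h2.pairs, h2.pairs[1:]):
            if i2 - i1 == 2 and j1 - j2 == 2 and seq[i1 + 1] == "U" and seq[j1 - 1] == "U":
                seq[i1 + 1] = "A"
                found = True
        assert found
        mutant = annotate_helices(ITS2Structure("m", "".join(seq), sc.dotbracket))
        rep = validate_hallmarks(mutant)
        assert not rep.helixII_UU
        assert rep.four_helices and rep.yggy_helixIII_5prime_apex

    def test_mutating_motif_to_aggA_fails_only_yggy(self):
        sc = make_scaffold()
        s = annotate_helices(sc.structure("s"))
        win = helix_iii_apex_window(s)
        seq = list(sc.sequence)
        m = next(p for p in find_yggy(sc.sequence) if win[0] <= p < win[1])
        # UGGU -> AGGA; partners change U<->A to keep pairing canonical
        pm = s.pair_map
        for k in (m, m + 3):
            seq[k] = "A"
            seq[pm[k]] = "U"
        mutant = annotate_helices(ITS2Structure("m", "".join(seq), sc.dotbracket))
        rep = validate_hallmarks(mutant)
        assert not rep.yggy_helixIII_5prime_apex
        assert rep.four_helices and rep.helixII_UU


class TestYggy:
    @pytest.mark.parametrize("seq,expect", [
        ("AUGGUA", [1]),
        ("CGGC", [0]),
        ("AGGA", []),
        ("UGGUGGU", [0, 3]),  # overlapping region, both reported
    ])
    def test_motif_matches(self, seq, expect):
        assert find_yggy(seq) == expect


def _swap_pair(sc, seq, pair, new):
    i, j = pair
    s = list(seq)
    s[i], s[j] = new
    return "".join(s)


class TestCBC:
    def test_definition_cases(self):
        sc = make_scaffold()
        a = annotate_helices(sc.structure("a"))
        # full CBC: A-U -> C-G at a helix-I pair (both bases change)
        p = a.helices[0].pairs[2]
        assert (a.sequence[p[0]], a.sequence[p[1]]) == ("A", "U")
        b_seq = _swap_pair(sc, sc.sequence, p, ("C", "G"))
        b = annotate_helices(ITS2Structure("b", b_seq, sc.dotbracket))
        rep = detect_cbc(a, b, global_align(a.sequence, b.sequence))
        assert (p, p) in rep.cbc_positions
        # hemi-CBC: A-U -> G-U (one base changes, pairing stays canonical)
        c_seq = _swap_pair(sc, sc.sequence, p, ("G", "U"))
        c = annotate_helices(ITS2Structure("c", c_seq, sc.dotbracket))
        rep2 = detect_cbc(a, c, global_align(a.sequence, c.sequence))
        assert (p, p) in rep2.hemi_cbc_positions
        assert not rep2.cbc_positions

    def test_matches_exhaustive_column_scan(self):
        sc = make_scaffold()
        a = annotate_helices(sc.structure("a"))
        seq = sc.sequence
        for pair, new in [(sc.window_pairs[0], ("U", "A")),
                          (sc.mutable_pairs[5], ("C", "G"))]:
            seq = _swap_pair(sc, seq, pair, new)
        b = annotate_helices(ITS2Structure("b", seq, sc.dotbracket))
        res = global_align(a.sequence, b.sequence)
        rep = detect_cbc(a, b, res)
        cbc, hemi = _oracles.cbc_scan(
            a.sequence, a.pairs, b.sequence, b.pairs,
            res.aligned_a, res.aligned_b)
        assert sorted(p for p, _ in rep.cbc_positions) == sorted(cbc)
        assert sorted(p for p, _ in rep.hemi_cbc_positions) == sorted(hemi)

    def test_symmetry(self):
        sc = make_scaffold()
        a = annotate_helices(sc.structure("a"))
        b_seq = _swap_pair(sc, sc.sequence, sc.window_pairs[1], ("A", "U"))
        b = annotate_helices(ITS2Structure("b", b_seq, sc.dotbracket))
        r_ab = detect_cbc(a, b, global_align(a.sequence, b.sequence))
        r_ba = detect_cbc(b, a, global_align(b.sequence, a.sequence))
        assert len(r_ab.cbc_positions) == len(r_ba.cbc_positions)
        assert r_ab.same_species == r_ba.same_species
        assert [(pb, pa) for pa, pb in r_ab.cbc_positions] == r_ba.cbc_positions


class TestDelimitation:
    def _structs(self):
        sc = make_scaffold()
        a = annotate_helices(sc.structure("a"))
        # same species as a: identical sequence
        b = annotate_helices(sc.structure("b"))
        # CBC inside the helix-III apex window -> distinct species
        c_seq = _swap_pair(sc, sc.sequence, sc.window_pairs[0], ("C", "G"))
        c = annotate_helices(ITS2Structure("c", c_seq, sc.dotbracket))
        # CBC only in helix I -> same species as a
        d_seq = _swap_pair(sc, sc.sequence, a.helices[0].pairs[4], ("U", "A"))
        d = annotate_helices(ITS2Structure("d", d_seq, sc.dotbracket))
        return {"a": a, "b": b, "c": c, "d": d}

    def test_partition(self):
        structs = self._structs()
        align = lambda x, y: global_align(x, y)
        species = delimit_species(list(structs), structs, align)
        flat = sorted(x for comp in species for x in comp)
        assert flat == ["a", "b", "c", "d"]  # every OTU in exactly one species
        by = {x: i for i, comp in enumerate(species) for x in comp}
        assert by["a"] == by["b"] == by["d"]
        assert by["c"] != by["a"]

    def test_missing_structure_becomes_own_species(self):
        structs = self._structs()
        species = delimit_species(["a", "b", "zzz"], structs,
                                  lambda x, y: global_align(x, y))
        assert ["zzz"] in species


def test_vienna_roundtrip(tmp_path):
    sc = make_scaffold()
    s = sc.structure("tmpl1")
    path = tmp_path / "s.vienna"
    write_vienna([s], path)
    back = read_vienna(path)
    assert len(back) == 1
    assert back[0].name == "tmpl1"
    assert back[0].sequence == to_rna(sc.sequence)
    assert back[0].dotbracket == sc.dotbracket
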