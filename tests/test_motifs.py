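import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import naive_scan_starts

from utrx import (
    BUILTIN_MOTIFS,
    MotifParseError,
    ValidationError,
    count_motifs,
    count_seed_sites,
    parse_motif_pattern,
    scan_motif,
)
from utrx.motifs import Gap, Repeat, Word


class TestParse:
    def test_single_iupac_word(self):
        pat = parse_motif_pattern("UAUUUAUWW")
        (word,) = pat.elements
        assert isinstance(word, Word)
        assert len(word.variants) == 1 and len(word.variants[0]) == 9

    def test_word_gap_word(self):
        pat = parse_motif_pattern("UUUUAU 1.100 AAUAAA")
        assert [type(e) for e in pat.elements] == [Word, Gap, Word]
        gap = pat.elements[1]
        assert (gap.min, gap.max) == (1, 100)

    def test_bounded_repeat(self):
        pat = parse_motif_pattern("Y{0,4}")
        (rep,) = pat.elements
        assert isinstance(rep, Repeat)
        assert (rep.min, rep.max) == (0, 4)
        assert rep.allowed == frozenset("CT")

    def test_alternation_expands_variants(self):
        pat = parse_motif_pattern("A(A|U)UAAA")
        (word,) = pat.elements
        assert len(word.variants) == 2

    def test_mismatch_triple_attaches_to_preceding_word(self):
        pat = parse_motif_pattern("KKKKKKKKKK [5,0,0]")
        (word,) = pat.elements
        assert word.mismatch == (5, 0, 0)

    def test_the_four_builtin_patterns_parse(self):
        assert set(BUILTIN_MOTIFS) == {
            "c_rich", "au_rich", "cyto_polyA", "mammalian_polyA"
        }
        c_rich = BUILTIN_MOTIFS["c_rich"]
        assert [type(e) for e in c_rich.elements] == [Word, Gap, Word, Repeat, Word]

    @pytest.mark.parametrize(
        "bad", ["AC(GT", "5...2", "Y{4,0}", "[1,0,0]", "AXC", ""]
    )
    def test_malformed_patterns_raise_with_position(self, bad):
        with pytest.raises(MotifParseError):
            parse_motif_pattern(bad)


class TestScan:
    def test_au_rich_direct_match(self):
        hits = scan_motif("UAUUUAUAA", BUILTIN_MOTIFS["au_rich"])
        assert hits == [(0, 9)]

    def test_au_rich_w_excludes_g(self):
        assert scan_motif("UAUUUAUGG", BUILTIN_MOTIFS["au_rich"]) == []

    def test_c_rich_compound_match(self):
        # YCCA="CCCA", zero gap, CCCW="CCCA", zero Ys, TCYCC="UCUCC"
        hits = scan_motif("CCCACCCAUCUCC", BUILTIN_MOTIFS["c_rich"])
        assert (0, 13) in hits

    def test_mammalian_polyA_with_plain_k_run(self):
        seq = "AAUAAA" + "GCGCACGTACGA"[:12] + "GUGUGUGUGU"
        hits = scan_motif(seq, BUILTIN_MOTIFS["mammalian_polyA"])
        assert hits and hits[0][0] == 0

    def test_mammalian_polyA_tolerates_five_substitutions_in_k_run(self):
        seq = "AUUAAA" + "A" * 12 + "GUGUG" + "AACCA"  # 5 non-K bases
        assert scan_motif(seq, BUILTIN_MOTIFS["mammalian_polyA"])
        seq_bad = "AUUAAA" + "A" * 12 + "GUGU" + "AACCAA"  # 6 non-K bases
        assert not scan_motif(seq_bad, BUILTIN_MOTIFS["mammalian_polyA"])

    def test_sequence_n_matches_only_pattern_n(self):
        assert scan_motif("ANA", parse_motif_pattern("ANA")) == [(0, 3)]
        assert scan_motif("ANA", parse_motif_pattern("AAA")) == []
        assert scan_motif("ANA", parse_motif_pattern("AWA")) == []

    def test_insertion_and_deletion_allowances(self):
        # one insertion: extra base inside the word
        pat_ins = parse_motif_pattern("ACGT [0,1,0]")
        assert (0, 5) in scan_motif("ACGGT", pat_ins)
        assert scan_motif("ACGGT", parse_motif_pattern("ACGT")) == []
        # one deletion: word base missing from the sequence
        pat_del = parse_motif_pattern("ACGT [0,0,1]")
        assert (0, 3) in scan_motif("AGT", pat_del)

    @pytest.mark.parametrize("name", sorted(BUILTIN_MOTIFS))
    def test_matches_naive_enumerator_on_random_sequences(self, name):
        import zlib

        pattern = BUILTIN_MOTIFS[name]
        rng = np.random.default_rng(zlib.crc32(name.encode()) % 2**31)
        bases = np.array(list("ACGT"))
        # enriched alphabet mixes so every pattern gets real hits sometimes
        probs = [(0.25, 0.25, 0.25, 0.25), (0.4, 0.1, 0.1, 0.4),
                 (0.15, 0.35, 0.15, 0.35)]
        for i in range(60):
            p = probs[i % len(probs)]
            seq = "".join(rng.choice(bases, size=200, p=p))
            ours = [start for start, _ in scan_motif(seq, pattern)]
            assert ours == naive_scan_starts(seq, pattern)


class TestSeedSites:
    def test_7mer_m8_is_reverse_complement_of_seed(self):
        counts = count_seed_sites("GGCUACCUCGG", ["GAGGUAG"])["GAGGUAG"]
        assert counts == {"8mer": 0, "7mer-m8": 1, "7mer-A1": 0}

    def test_trailing_a_upgrades_to_8mer_without_double_count(self):
        counts = count_seed_sites("GGCUACCUCAGG", ["GAGGUAG"])["GAGGUAG"]
        assert counts == {"8mer": 1, "7mer-m8": 0, "7mer-A1": 0}

    def test_7mer_a1_matches_positions_2_to_7_plus_a(self):
        # UACCUC (revcomp of GAGGUA) + A, without the full m8 match upstream
        counts = count_seed_sites("GGUACCUCAGG", ["GAGGUAG"])["GAGGUAG"]
        assert counts == {"8mer": 0, "7mer-m8": 0, "7mer-A1": 1}

    def test_empty_target_counts_zero(self):
        counts = count_seed_sites("", ["GAGGUAG"])["GAGGUAG"]
        assert counts == {"8mer": 0, "7mer-m8": 0, "7mer-A1": 0}

    def test_non_7mer_seed_rejected(self):
        with pytest.raises(ValidationError):
            count_seed_sites("ACGU", ["GAGGUA"])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=20, max_size=120),
           st.text(alphabet="ACGU", min_size=7, max_size=7))
    def test_seed_match_duality_with_plain_substring_count(self, target, seed):
        """Seed matches are revcomp(seed) in the target, i.e. the seed itself
        read on the reverse-complemented target — cross-check with a plain
        overlapping substring count."""
        comp = str.maketrans("ACGU", "UGCA")
        rc_target = target.translate(comp)[::-1]

        def occurrences(hay, needle):
            n, i = 0, hay.find(needle)
            while i >= 0:
                n += 1
                i = hay.find(needle, i + 1)
            return n

        counts = count_seed_sites(target, [seed])[seed]
        assert counts["8mer"] + counts["7mer-m8"] == occurrences(rc_target, seed)


def test_count_motifs_per_kbp():
    table = count_motifs(
        {"a": ["UAUUUAUAA" + "C" * 91], "b": ["C" * 100]},
        {"au_rich": BUILTIN_MOTIFS["au_rich"]},
    )
    assert table.counts["a"]["au_rich"] == 1
    assert table.counts["b"]["au_rich"] == 0
    assert table.total_bp["a"] == 100
    assert table.per_kbp("a", "au_rich") == pytest.approx(10.0)
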