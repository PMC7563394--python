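import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from _oracles import double_loop_motif_counts, exact_fisher_two_sided
from conftest import make_utr, random_dna
from seedshift.io_formats import VariantRecord
from seedshift.motif_stats import (count_motif, extract_window,
                                   fisher_exact_two_sided,
                                   fisher_presence_test,
                                   iid_presence_expectation,
                                   motif_presence_test, read_meme_consensus,
                                   write_windows_fasta)


class TestExtractWindow:
    def test_centered_window_even_width(self):
        utr = make_utr("A" * 200, start=1001)
        v = VariantRecord("1", 1060, "A", "G")  # UTR offset 60
        w = extract_window(utr, v, width=100)
        assert len(w.sequence) == 100
        assert w.offset_of_variant == 50
        assert w.sequence == utr.sequence[10:110]  # offsets 11-110

    def test_clipped_at_utr_start(self):
        utr = make_utr("ACGTACGTACGT", start=1001)
        v = VariantRecord("1", 1003, "G", "C")  # offset 3
        w = extract_window(utr, v, width=100)
        assert w.sequence == utr.sequence
        assert w.offset_of_variant == 3

    def test_unclipped_window_has_exact_width(self):
        utr = make_utr("C" * 400, start=1001)
        v = VariantRecord("1", 1200, "C", "T")
        assert len(extract_window(utr, v, width=100).sequence) == 100

    def test_variant_outside_utr_rejected(self):
        utr = make_utr("ACGT", start=1001)
        with pytest.raises(ValueError, match="outside"):
            extract_window(utr, VariantRecord("1", 99, "A", "G"))

    def test_windows_fasta_roundtrip(self, tmp_path):
        utr = make_utr("ACGTACGTACGTACGT", start=1001)
        w = extract_window(utr, VariantRecord("1", 1008, "T", "A"), width=6)
        path = tmp_path / "w.fa"
        write_windows_fasta([w], path)
        from Bio import SeqIO
        (rec,) = list(SeqIO.parse(str(path), "fasta"))
        assert str(rec.seq) == w.sequence


class TestCountMotif:
    def test_overlapping_occurrences_and_presence(self):
        utrs = [make_utr("AAAA"), make_utr("CCCC")]
        assert count_motif("AA", utrs) == (1, 3, 2)

    def test_presence_via_reverse_complement(self):
        assert count_motif("AC", [make_utr("GT")]) == (1, 1, 1)

    def test_empty_set(self):
        assert count_motif("AA", []) == (0, 0, 0)

    def test_palindrome_counted_once_per_offset(self):
        # revcomp("AT") == "AT": offsets 1 and 3 of "ATAT", not doubled
        assert count_motif("AT", [make_utr("ATAT")]) == (1, 2, 1)

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_motif("", [make_utr("ACGT")])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            seqs = [random_dna(rng, int(rng.integers(1, 80)))
                    for _ in range(int(rng.integers(1, 12)))]
            motif = random_dna(rng, int(rng.integers(1, 7)))
            got = count_motif(motif, [make_utr(s) for s in seqs])
            assert got == double_loop_motif_counts(motif, seqs)


class TestFisher:
    def test_single_observation_each_way(self):
        assert fisher_exact_two_sided(1, 0, 0, 1) == pytest.approx(1.0)

    def test_identical_rows_give_p_one(self):
        res = fisher_presence_test(5, 10, (5, 10))
        assert res.p_value == pytest.approx(1.0)

    def test_eight_two_table_matches_enumeration_oracle(self):
        mine = fisher_exact_two_sided(8, 2, 2, 8)
        assert mine == pytest.approx(float(exact_fisher_two_sided(8, 2, 2, 8)),
                                     abs=1e-12)

    @settings(deadline=None, max_examples=150)
    @given(st.tuples(st.integers(0, 30), st.integers(0, 30),
                     st.integers(0, 30), st.integers(0, 30)))
    def test_matches_oracle_and_scipy_and_row_swap(self, table):
        a, b, c, d = table
        mine = fisher_exact_two_sided(a, b, c, d)
        assert mine == pytest.approx(float(exact_fisher_two_sided(a, b, c, d)),
                                     abs=1e-12)
        assert mine == pytest.approx(fisher_exact([[a, b], [c, d]]).pvalue,
                                     abs=1e-9)
        assert mine == pytest.approx(fisher_exact_two_sided(c, d, a, b),
                                     abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_presence_test(5, 3, (1, 2))
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 1, 1, 1)


class TestPresenceTest:
    def test_control_mode_uses_background_counts(self):
        fg = [make_utr("TTAACATCAA" + "G" * 20) for _ in range(4)]
        bg = [make_utr("G" * 30) for _ in range(4)]
        res = motif_presence_test("TTAACATCAA", fg, bg)
        assert res.mode == "control"
        assert res.n_present == 4 and res.n_total == 4
        assert res.p_value == pytest.approx(
            float(exact_fisher_two_sided(4, 0, 0, 4)), abs=1e-12)

    def test_iid_mode_expectation(self):
        utrs = [make_utr("ACGT" * 25) for _ in range(10)]
        expected = iid_presence_expectation("ACG", utrs)
        res = motif_presence_test("ACG", utrs)
        assert res.mode == "iid"
        assert res.expected_present == pytest.approx(expected)
        assert 0 <= res.p_value <= 1


def test_meme_consensus_extraction(tmp_path):
    meme = """MEME version 4

ALPHABET= ACGT

MOTIF M1 test
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 1e-5
0.90 0.05 0.03 0.02
0.01 0.02 0.02 0.95
0.10 0.60 0.20 0.10
"""
    p = tmp_path / "m.meme"
    p.write_text(meme)
    assert read_meme_consensus(p) == ["ATC"]
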