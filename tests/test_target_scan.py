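import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_seed_matches
from conftest import make_utr, random_dna
from seedshift.io_formats import VariantRecord
from seedshift.target_scan import (MatureMiRNA, SeedMatch, apply_variant,
                                   classify_snv_effect, find_seed_matches,
                                   seed_site_strings, tally_classifications,
                                   tally_variants)

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)
rna8plus = st.text(alphabet="ACGU", min_size=8, max_size=25)


class TestSeedSiteStrings:
    def test_toy_mirna_all_four_types(self, toy_mirna):
        assert seed_site_strings(toy_mirna) == {
            "6mer": "TACTTG", "7mer-m8": "ATACTTG",
            "7mer-A1": "TACTTGA", "8mer": "ATACTTGA"}

    def test_poly_a_mirna_complement_symmetry(self):
        m = MatureMiRNA("polyA", "AAAAAAAA")
        assert seed_site_strings(m)["6mer"] == "TTTTTT"

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="shorter than 8"):
            MatureMiRNA("short", "UCAAGUA")

    @settings(deadline=None)
    @given(seq=rna8plus)
    def test_site_strings_pair_with_seed(self, seq):
        """Each site string base-pairs the corresponding seed positions."""
        m = MatureMiRNA("x", seq)
        strings = seed_site_strings(m)
        pairs = {("A", "U"), ("C", "G"), ("G", "C"), ("T", "A")}
        s8 = strings["8mer"]
        assert s8[-1] == "A" and len(s8) == 8
        # 8mer chars 1..7 pair miRNA positions 8..2
        assert all((s8[k], seq[7 - k]) in pairs for k in range(7))
        assert strings["7mer-m8"] == s8[:7]
        assert strings["7mer-A1"] == s8[1:7] + "A" == strings["6mer"] + "A"


class TestFindSeedMatches:
    def test_single_8mer(self, toy_mirna):
        utr = make_utr("GGGATACTTGAGGG")
        assert find_seed_matches(utr, toy_mirna) == [
            SeedMatch("toy", "8mer", 4, 11)]

    def test_no_complementarity(self, toy_mirna):
        assert find_seed_matches(make_utr("CCCCCCCC"), toy_mirna) == []

    def test_bare_6mer(self, toy_mirna):
        utr = make_utr("TACTTGC")
        assert find_seed_matches(utr, toy_mirna) == [
            SeedMatch("toy", "6mer", 1, 6)]

    def test_hierarchy_8mer_masks_weaker_types(self, toy_mirna):
        """Ignoring 8mers must reveal a 7mer at the same locus."""
        utr = make_utr("GGGATACTTGAGGG")
        weaker = find_seed_matches(utr, toy_mirna,
                                   site_types=("7mer-m8", "7mer-A1", "6mer"))
        types = {(m.site_type, m.utr_start) for m in weaker}
        assert ("7mer-m8", 4) in types and ("7mer-A1", 5) in types

    def test_matches_brute_force_on_random_utrs(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            seq = random_dna(rng, int(rng.integers(6, 201)))
            mirna = MatureMiRNA("m", "".join(
                rng.choice(list("ACGU"), size=int(rng.integers(8, 23)))))
            got = [(m.site_type, m.utr_start, m.utr_end)
                   for m in find_seed_matches(make_utr(seq), mirna)]
            assert got == brute_force_seed_matches(seq, mirna.sequence)


class TestApplyVariant:
    def test_plus_strand_substitution(self):
        utr = make_utr("GGGATACTTGAGGG", start=101)
        v = VariantRecord("1", 107, "C", "G")
        assert apply_variant(utr, v).sequence == "GGGATAGTTGAGGG"
        assert utr.sequence == "GGGATACTTGAGGG"  # original untouched

    def test_minus_strand_mirrored_complement(self):
        # plus-strand genomic 101..114 = revcomp of the mRNA-sense UTR
        utr = make_utr("GGGATACTTGAGGG", strand="-", start=101)
        # genomic pos 107 maps to mRNA offset 114-107+1 = 8 ('T'); its
        # plus-strand base is the complement 'A'
        v = VariantRecord("1", 107, "A", "C")
        out = apply_variant(utr, v)
        assert out.sequence == "GGGATACGTGAGGG"

    def test_reference_mismatch_raises(self):
        utr = make_utr("GGGATACTTGAGGG", start=101)
        with pytest.raises(ValueError, match="reference mismatch"):
            apply_variant(utr, VariantRecord("1", 107, "A", "G"))

    def test_position_outside_span_raises(self):
        utr = make_utr("GGGA", start=101)
        with pytest.raises(ValueError, match="outside"):
            apply_variant(utr, VariantRecord("1", 300, "A", "G"))

    @settings(deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=1, max_size=60),
           data=st.data())
    def test_involution_alt_then_ref_restores(self, seq, data):
        pos0 = data.draw(st.integers(0, len(seq) - 1))
        alt = data.draw(st.sampled_from([b for b in "ACGT"
                                         if b != seq[pos0]]))
        utr = make_utr(seq, start=1000)
        v = VariantRecord("1", 1000 + pos0, seq[pos0], alt)
        back = VariantRecord("1", 1000 + pos0, alt, seq[pos0])
        assert apply_variant(apply_variant(utr, v), back).sequence == seq


def test_strand_mirror_detection(toy_mirna):
    """A site planted on a minus-strand gene is found with the same type and
    mRNA-relative span as its plus-strand mirror construction."""
    sense = "GGGATACTTGAGGG"
    plus = make_utr(sense, strand="+", start=201)
    from seedshift.io_formats import reverse_complement
    minus = make_utr(sense, strand="-", start=201)  # same mRNA-sense string
    got_plus = find_seed_matches(plus, toy_mirna)
    got_minus = find_seed_matches(minus, toy_mirna)
    assert got_plus == got_minus == [SeedMatch("toy", "8mer", 4, 11)]
    # and the genomic footprints mirror each other within the span
    assert plus.offset_to_genomic(4) - 201 == 214 - minus.offset_to_genomic(4)


class TestClassify:
    def test_loss_when_site_destroyed(self, toy_mirna):
        utr = make_utr("GGGATACTTGAGGG", start=101)  # 8mer at offsets 4-11
        v = VariantRecord("1", 110, "G", "C")        # offset 10, inside site
        change = classify_snv_effect(utr, v, "toy", [toy_mirna])
        assert change.classification == "loss"
        assert change.ref_sites and not change.alt_sites
        assert change.gained_mirnas == ()

    def test_gain_for_second_library_mirna(self, toy_mirna):
        other = MatureMiRNA("other", "UGGGUGGGA")  # 6mer site: CCACCC
        utr = make_utr("TTTCCACCGTTTTT", start=101)
        v = VariantRecord("1", 109, "G", "C")  # offset 9: CCACCG -> CCACCC
        change = classify_snv_effect(utr, v, "toy", [toy_mirna, other])
        assert change.classification == "gain"
        assert change.gained_mirnas == ("other",)

    def test_substitution_paired_loss_plus_other_gain(self, toy_mirna):
        # alt allele turns the toy 8mer ATACTTGA into ATACTAGA, a 6mer
        # (TACTAG) site for a crafted second miRNA
        crafted = MatureMiRNA("crafted", "ACUAGUAAA")
        utr = make_utr("GGGATACTTGAGGG", start=101)
        v = VariantRecord("1", 109, "T", "A")  # offset 9
        change = classify_snv_effect(utr, v, "toy", [toy_mirna, crafted])
        assert change.classification == "substitution"
        assert "crafted" in change.gained_mirnas

    def test_none_when_sites_unchanged(self, toy_mirna):
        utr = make_utr("CCCCCCCCCCCCCC", start=101)
        v = VariantRecord("1", 103, "C", "G")
        change = classify_snv_effect(utr, v, "toy", [toy_mirna])
        assert change.classification == "none"
        assert change.ref_sites == change.alt_sites == ()

    def test_unknown_paired_mirna_rejected(self, toy_mirna):
        utr = make_utr("CCCCCCCC", start=101)
        with pytest.raises(KeyError):
            classify_snv_effect(utr, VariantRecord("1", 103, "C", "G"),
                                "ghost", [toy_mirna])


class TestTallies:
    def test_counts_per_classification(self, toy_mirna):
        utr = make_utr("GGGATACTTGAGGGTTTCCCACGTTTTT" + "C" * 20, start=101)
        changes = [
            classify_snv_effect(utr, VariantRecord("1", 110, "G", "C"),
                                "toy", [toy_mirna]),           # loss
            classify_snv_effect(utr, VariantRecord("1", 130, "C", "G"),
                                "toy", [toy_mirna]),           # none
        ]
        tally = tally_classifications(changes)
        assert tally["loss"] == 1 and tally["none"] == 1
        assert sum(tally[k] for k in
                   ("loss", "gain", "substitution", "none")) == len(changes)

    def test_empty_list_all_zero(self):
        assert tally_classifications([]) == {
            "loss": 0, "gain": 0, "substitution": 0, "none": 0,
            "with_alternative": 0}

    def test_variant_level_reduction_prefers_severity(self, toy_mirna):
        """The same variant classified against two pairs counts once, under
        the most severe call."""
        other = MatureMiRNA("other", "UGGGUGGGAUCC")
        utr = make_utr("GGGATACTTGAGGG", start=101)
        v = VariantRecord("1", 110, "G", "C")
        changes = [classify_snv_effect(utr, v, "toy", [toy_mirna, other]),
                   classify_snv_effect(utr, v, "other", [toy_mirna, other])]
        assert {c.classification for c in changes} == {"loss", "none"}
        t = tally_variants(changes)
        assert t["loss"] == 1 and t["none"] == 0
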