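import numpy as np
import pytest

from _oracles import brute_force_region_calls
from seedshift.io_formats import TranscriptModel, VariantRecord
from seedshift.region_filter import (audit_table, call_region,
                                     filter_exclusive)


def model(tid, gene="G1", chrom="1", strand="+", regions=()):
    return TranscriptModel(transcript_id=tid, gene_symbol=gene, chrom=chrom,
                           strand=strand, regions=tuple(regions))


T1 = model("T1", regions=[("five_prime_utr", 1, 100), ("cds", 101, 500),
                          ("three_prime_utr", 501, 900)])
T2 = model("T2", regions=[("five_prime_utr", 1, 100), ("cds", 101, 700),
                          ("three_prime_utr", 701, 900)])


class TestCallRegion:
    def test_single_transcript_3utr_is_exclusive(self):
        call = call_region(VariantRecord("1", 800, "A", "G"), [T1])
        assert call.exclusive_3utr
        assert call.covering_transcripts == (("T1", "three_prime_utr"),)

    def test_isoform_dependent_position_not_exclusive(self):
        # 3'UTR of T1 but CDS of the longer-CDS isoform T2
        call = call_region(VariantRecord("1", 600, "A", "G"), [T1, T2])
        assert not call.exclusive_3utr
        assert dict(call.covering_transcripts) == {
            "T1": "three_prime_utr", "T2": "cds"}

    def test_uncovered_position_not_exclusive(self):
        call = call_region(VariantRecord("1", 5000, "A", "G"), [T1, T2])
        assert call.covering_transcripts == ()
        assert not call.exclusive_3utr

    def test_gap_inside_footprint_is_unannotated(self):
        gappy = model("T3", regions=[("cds", 101, 500),
                                     ("three_prime_utr", 601, 900)])
        call = call_region(VariantRecord("1", 550, "A", "G"), [gappy])
        assert call.covering_transcripts == (("T3", "unannotated"),)
        assert not call.exclusive_3utr

    def test_chr_prefix_insensitive(self):
        call = call_region(VariantRecord("chr1", 800, "A", "G"), [T1])
        assert call.exclusive_3utr


class TestFilterExclusive:
    def test_split_is_a_partition(self):
        variants = [VariantRecord("1", p, "A", "G")
                    for p in (600, 800, 5000)]
        kept, dropped = filter_exclusive(variants, [T1, T2])
        assert len(kept) + len(dropped) == len(variants)
        assert [v.pos for v in kept] == [800]
        assert kept[0].gene == "G1"

    def test_empty_input(self):
        assert filter_exclusive([], [T1]) == ([], [])

    def test_all_exclusive_means_nothing_dropped(self):
        variants = [VariantRecord("1", p, "A", "G") for p in (750, 800)]
        kept, dropped = filter_exclusive(variants, [T2])
        assert dropped == [] and len(kept) == 2

    def test_two_gene_ambiguity_dropped(self, caplog):
        other_gene = model("T9", gene="G2", regions=[
            ("three_prime_utr", 700, 1000)])
        with caplog.at_level("WARNING", logger="seedshift.region_filter"):
            kept, dropped = filter_exclusive(
                [VariantRecord("1", 800, "A", "G")], [T1, other_gene])
        assert kept == [] and len(dropped) == 1
        assert any("ambiguous" in r.message for r in caplog.records)

    def test_monotone_adding_cds_isoform_only_removes(self):
        v = VariantRecord("1", 600, "A", "G")
        kept1, _ = filter_exclusive([v], [T1])
        kept2, _ = filter_exclusive([v], [T1, T2])
        assert [x.pos for x in kept1] == [600] and kept2 == []


def test_matches_triple_enumeration_oracle():
    """Region calls equal a brute-force enumeration over every
    (variant, transcript, interval) triple on random instances."""
    rng = np.random.default_rng(11)
    kinds = ["five_prime_utr", "cds", "three_prime_utr"]
    for _ in range(30):
        models = []
        for t in range(int(rng.integers(1, 50))):
            lo = int(rng.integers(1, 2000))
            regions = []
            for k in rng.permutation(kinds)[: int(rng.integers(1, 4))]:
                width = int(rng.integers(1, 300))
                regions.append((str(k), lo, lo + width - 1))
                lo += width + int(rng.integers(0, 50))  # optional gap
            models.append(model(f"T{t}", gene=f"G{t % 5}",
                                chrom=str(rng.integers(1, 4)),
                                regions=regions))
        for _ in range(20):
            v = VariantRecord(str(rng.integers(1, 4)),
                              int(rng.integers(1, 4000)), "A", "G")
            expected_calls, expected_flag = brute_force_region_calls(
                v.pos, v.chrom, models)
            got = call_region(v, models)
            assert list(got.covering_transcripts) == expected_calls
            assert got.exclusive_3utr == expected_flag


def test_audit_table_lists_every_covering_transcript():
    df = audit_table([VariantRecord("1", 600, "A", "G"),
                      VariantRecord("1", 5000, "A", "G")], [T1, T2])
    assert set(df["region_kind"]) == {"three_prime_utr", "cds", "uncovered"}
    assert (~df["exclusive_3utr"]).all()
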