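"""Canonical miRNA seed matching and allele-aware variant classification.

This is the predictive core of the pipeline: a TargetScan-style canonical
seed matcher (8mer, 7mer-m8, 7mer-A1, 6mer; Watson-Crick pairing only, no
G:U wobble, no 3'-supplementary pairing, no context scoring) used as a
reproducible stand-in for precomputed miRNA-target-site variant databases.

A single-nucleotide variant in a 3'UTR is classified into one of three
damage scenarios, plus "none":

* ``loss``          — the paired miRNA's site over the variant is destroyed
                      and no other library miRNA gains a site there;
* ``substitution``  — the paired miRNA's site is destroyed and a different
                      library miRNA gains a site over the variant;
* ``gain``          — the paired miRNA had no site over the variant and some
                      library miRNA acquires one on the alternate allele;
* ``none``          — the overlapping site sets are otherwise unchanged.

Seed conventions: the seed is nucleotides 2-8 from the miRNA 5' end.  The
target-site strings, written 5'->3' in mRNA-sense DNA, are

* 6mer     = reverse complement of miRNA positions 2-7
* 7mer-m8  = reverse complement of miRNA positions 2-8
* 7mer-A1  = 6mer followed by ``A``
* 8mer     = 7mer-m8 followed by ``A``

U and T are treated as equivalent at comparison time: UTRs are stored as
DNA, miRNAs as RNA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import UTRSequence, VariantRecord, complement_base

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")  # strongest first
_STRENGTH = {t: i for i, t in enumerate(SITE_TYPES)}

_RNA_TO_DNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")

CLASSIFICATIONS = ("loss", "gain", "substitution", "none")


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA, 5'->3' RNA; the seed is positions 2-8."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence
        if not set(seq) <= set("ACGU"):
            raise ValueError(f"{self.name}: sequence must be RNA (ACGU), got "
                             f"{seq!r}")
        if len(seq) < 8:
            raise ValueError(f"{self.name}: mature miRNA shorter than 8 nt")

    @property
    def seed(self) -> str:
        """Positions 2-8 (1-based) from the 5' end."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class SeedMatch:
    """One predicted target site on an mRNA-sense UTR (1-based inclusive)."""

    mirna_name: str
    site_type: str
    utr_start: int
    utr_end: int

    def __post_init__(self):
        expected = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}
        if self.site_type not in expected:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.utr_end - self.utr_start + 1 != expected[self.site_type]:
            raise ValueError(f"{self.site_type} span must be "
                             f"{expected[self.site_type]} nt")

    def overlaps(self, offset: int) -> bool:
        return self.utr_start <= offset <= self.utr_end


@dataclass(frozen=True)
class TargetChange:
    """Per-(variant, curated pair) classification with the site evidence."""

    variant: VariantRecord
    gene_symbol: str
    paired_mirna: str
    classification: str
    ref_sites: tuple[SeedMatch, ...]
    alt_sites: tuple[SeedMatch, ...]
    gained_mirnas: tuple[str, ...]


def _revcomp_rna_as_dna(rna: str) -> str:
    """Reverse complement of an RNA string, written as DNA (target sense)."""
    return rna.translate(_RNA_TO_DNA_COMPLEMENT)[::-1]


def seed_site_strings(mirna: MatureMiRNA) -> dict[str, str]:
    """The four canonical target-site strings for a miRNA, mRNA-sense DNA."""
    six = _revcomp_rna_as_dna(mirna.sequence[1:7])      # positions 2-7
    seven_m8 = _revcomp_rna_as_dna(mirna.sequence[1:8])  # positions 2-8
    return {
        "8mer": seven_m8 + "A",
        "7mer-m8": seven_m8,
        "7mer-A1": six + "A",
        "6mer": six,
    }


def _occurrences(haystack: str, needle: str) -> Iterable[int]:
    """All 0-based start offsets of needle in haystack, overlaps allowed."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def find_seed_matches(utr: UTRSequence, mirna: MatureMiRNA,
                      site_types: Sequence[str] = SITE_TYPES
                      ) -> list[SeedMatch]:
    """All canonical seed matches of one miRNA on an mRNA-sense UTR.

    At a given locus only the strongest applicable type is reported: a
    weaker match whose span is contained in a stronger match's span is
    suppressed (e.g. the 7mer-m8 and 6mer inside every 8mer).  Distinct
    loci may overlap each other.
    """
    strings = seed_site_strings(mirna)
    seq = utr.sequence
    matches: list[SeedMatch] = []
    for site_type in sorted(site_types, key=_STRENGTH.get):
        needle = strings[site_type]
        for i in _occurrences(seq, needle):
            start, end = i + 1, i + len(needle)
            if any(m.utr_start <= start and end <= m.utr_end for m in matches):
                continue  # contained in an already-reported stronger site
            matches.append(SeedMatch(mirna_name=mirna.name, site_type=site_type,
                                     utr_start=start, utr_end=end))
    matches.sort(key=lambda m: (m.utr_start, _STRENGTH[m.site_type]))
    return matches


def apply_variant(utr: UTRSequence, v: VariantRecord) -> UTRSequence:
    """Substitute one base of the UTR according to a genomic SNV.

    The variant's alleles are plus-strand; on minus-strand transcripts the
    mRNA-sense base is the complement of the allele.  The input is not
    modified.
    """
    offset = utr.genomic_to_offset(v.pos)
    if offset is None:
        raise ValueError(f"variant position {v.chrom}:{v.pos} outside the "
                         f"3'UTR span of {utr.transcript_id}")
    expected = v.ref if utr.strand == "+" else complement_base(v.ref)
    new = v.alt if utr.strand == "+" else complement_base(v.alt)
    observed = utr.sequence[offset - 1]
    if observed != expected:
        raise ValueError(
            f"reference mismatch at {v.chrom}:{v.pos} (UTR offset {offset} of "
            f"{utr.transcript_id}): expected {expected!r}, observed {observed!r}"
        )
    seq = utr.sequence[:offset - 1] + new + utr.sequence[offset:]
    return utr.with_sequence(seq)


def overlapping_sites(utr: UTRSequence, mirna: MatureMiRNA, offset: int
                      ) -> list[SeedMatch]:
    """Seed matches of one miRNA whose span contains the given UTR offset."""
    return [m for m in find_seed_matches(utr, mirna) if m.overlaps(offset)]


def classify_snv_effect(utr: UTRSequence, v: VariantRecord, paired_mirna: str,
                        mirna_library: Mapping[str, MatureMiRNA] |
                        Sequence[MatureMiRNA]) -> TargetChange:
    """Classify an SNV's effect on miRNA targeting of one curated pair.

    Only sites whose span contains the variant's UTR offset are considered.
    Gains are assessed against the whole miRNA library, not just the paired
    miRNA, so a variant can create a binding site for any known miRNA.
    """
    if not isinstance(mirna_library, Mapping):
        mirna_library = {m.name: m for m in mirna_library}
    if paired_mirna not in mirna_library:
        raise KeyError(f"paired miRNA {paired_mirna!r} not in library")

    offset = utr.genomic_to_offset(v.pos)
    if offset is None:
        raise ValueError(f"variant {v.chrom}:{v.pos} outside UTR "
                         f"{utr.transcript_id}")
    alt_utr = apply_variant(utr, v)

    ref_sites: list[SeedMatch] = []
    alt_sites: list[SeedMatch] = []
    gained: list[str] = []
    paired_ref = paired_alt = 0
    for name in sorted(mirna_library):
        mi = mirna_library[name]
        on_ref = overlapping_sites(utr, mi, offset)
        on_alt = overlapping_sites(alt_utr, mi, offset)
        ref_sites += on_ref
        alt_sites += on_alt
        if name == paired_mirna:
            paired_ref, paired_alt = len(on_ref), len(on_alt)
        if on_alt and not on_ref:
            gained.append(name)

    others_gained = [g for g in gained if g != paired_mirna]
    if paired_ref > 0 and paired_alt == 0:
        classification = "substitution" if others_gained else "loss"
    elif paired_ref == 0 and gained:
        classification = "gain"
    else:
        classification = "none"

    return TargetChange(
        variant=v, gene_symbol=utr.gene_symbol, paired_mirna=paired_mirna,
        classification=classification, ref_sites=tuple(ref_sites),
        alt_sites=tuple(alt_sites), gained_mirnas=tuple(gained),
    )


def tally_classifications(changes: Sequence[TargetChange]) -> dict[str, int]:
    """Summary counts per classification, plus the alternative-miRNA count.

    ``with_alternative`` counts changes with a non-empty ``gained_mirnas``
    (variants matched with alternative miRNAs); the four classification
    counts sum to ``len(changes)``.
    """
    counts = Counter(c.classification for c in changes)
    tally = {k: counts.get(k, 0) for k in CLASSIFICATIONS}
    tally["with_alternative"] = sum(1 for c in changes if c.gained_mirnas)
    return tally


def tally_variants(changes: Sequence[TargetChange]) -> dict[str, int]:
    """Variant-level tally: one classification per distinct variant.

    A gene may appear in several curated pairs, giving one TargetChange per
    pair; study-style accounting counts variants, so per-pair calls are
    reduced by severity (substitution > loss > gain > none).  A variant
    counts as "matched with alternative miRNAs" when any of its calls has a
    non-empty ``gained_mirnas``.
    """
    precedence = {"substitution": 0, "loss": 1, "gain": 2, "none": 3}
    best: dict[tuple, str] = {}
    gained: dict[tuple, bool] = {}
    for c in changes:
        k = c.variant.key
        if k not in best or precedence[c.classification] < precedence[best[k]]:
            best[k] = c.classification
        gained[k] = gained.get(k, False) or bool(c.gained_mirnas)
    counts = Counter(best.values())
    tally = {k: counts.get(k, 0) for k in CLASSIFICATIONS}
    tally["with_alternative"] = sum(gained.values())
    return tally


def build_library(mirna_sequences: Mapping[str, str]) -> dict[str, MatureMiRNA]:
    """Wrap {name: RNA sequence} (e.g. from a mature FASTA) into a library."""
    return {name: MatureMiRNA(name=name, sequence=seq)
            for name, seq in mirna_sequences.items()}
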