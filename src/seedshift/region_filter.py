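"""Isoform-wide 3'UTR exclusivity filter.

A variant is kept only when every transcript isoform that covers its
position annotates that position as 3'UTR.  A position can be 3'UTR in one
isoform and coding in another; such isoform-dependent variants are dropped,
as are variants covered by no transcript at all (no region information) and
variants whose covering transcripts disagree on the gene (ambiguous
assignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import TranscriptModel, VariantRecord, normalize_chrom

log = logging.getLogger(__name__)

# when several region kinds cover one base in one transcript, report the
# most protein-proximal one (never happens in well-formed annotations)
_KIND_PRIORITY = ("cds", "five_prime_utr", "three_prime_utr")


@dataclass(frozen=True)
class RegionCall:
    """Per-variant region annotation across all covering transcripts."""

    variant: VariantRecord
    covering_transcripts: tuple[tuple[str, str], ...]  # (transcript_id, kind)
    exclusive_3utr: bool
    gene_symbols: tuple[str, ...]  # distinct genes of covering transcripts


def call_region(v: VariantRecord, models: Sequence[TranscriptModel]
                ) -> RegionCall:
    """Region kind of a variant position in every transcript covering it.

    A transcript covers the variant iff the position falls inside its
    footprint; a covered position in no annotated interval is called
    ``unannotated`` and counts against exclusivity.
    """
    chrom = normalize_chrom(v.chrom)
    covering: list[tuple[str, str]] = []
    genes: list[str] = []
    for m in sorted(models, key=lambda m: m.transcript_id):
        if normalize_chrom(m.chrom) != chrom:
            continue
        lo, hi = m.footprint()
        if not lo <= v.pos <= hi:
            continue
        kinds = m.region_kinds_at(v.pos)
        if not kinds:
            kind = "unannotated"
        else:
            kind = min(kinds, key=_KIND_PRIORITY.index)
        covering.append((m.transcript_id, kind))
        if m.gene_symbol not in genes:
            genes.append(m.gene_symbol)
    exclusive = bool(covering) and all(k == "three_prime_utr"
                                       for _, k in covering)
    return RegionCall(variant=v, covering_transcripts=tuple(covering),
                      exclusive_3utr=exclusive, gene_symbols=tuple(genes))


def filter_exclusive(variants: Sequence[VariantRecord],
                     models: Sequence[TranscriptModel]
                     ) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into (kept, dropped) by the 3'UTR-exclusivity rule.

    Kept variants come back with the gene symbol of their covering
    transcripts filled in.  A variant whose covering transcripts belong to
    more than one gene is ambiguous and dropped with a logged reason.
    """
    kept: list[VariantRecord] = []
    dropped: list[VariantRecord] = []
    for v in variants:
        call = call_region(v, models)
        if not call.exclusive_3utr:
            dropped.append(v)
        elif len(call.gene_symbols) != 1:
            log.warning("variant %s:%d covered by transcripts of genes %s; "
                        "ambiguous, dropped", v.chrom, v.pos,
                        ",".join(call.gene_symbols))
            dropped.append(v)
        else:
            kept.append(v.with_gene(call.gene_symbols[0]))
    return kept, dropped


def audit_table(variants: Sequence[VariantRecord],
                models: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Per-variant, per-transcript region calls for the dropped-variant audit."""
    rows = []
    for v in variants:
        call = call_region(v, models)
        if not call.covering_transcripts:
            rows.append({"chr": v.chrom, "pos": v.pos, "ref": v.ref,
                         "alt": v.alt, "transcript_id": "",
                         "region_kind": "uncovered",
                         "exclusive_3utr": call.exclusive_3utr})
        for tid, kind in call.covering_transcripts:
            rows.append({"chr": v.chrom, "pos": v.pos, "ref": v.ref,
                         "alt": v.alt, "transcript_id": tid,
                         "region_kind": kind,
                         "exclusive_3utr": call.exclusive_3utr})
    return pd.DataFrame(rows, columns=["chr", "pos", "ref", "alt",
                                       "transcript_id", "region_kind",
                                       "exclusive_3utr"])
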