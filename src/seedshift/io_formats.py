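"""Readers, writers and core domain types for the 3'UTR variant pipeline.

Coordinate conventions
----------------------
All internal coordinates are 1-based inclusive on the genomic plus strand.
Dialect conversions (BED-like 0-based half-open, GTF 1-based inclusive)
happen only at file boundaries.  Chromosome labels are compared after
stripping an optional ``chr`` prefix, so mixed-source inputs interoperate.

UTR sequences are stored mRNA-sense (5'->3' of the transcript) as DNA; for
minus-strand transcripts the stored string is the reverse complement of the
plus-strand genomic sequence over the span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
REGION_KINDS = ("five_prime_utr", "cds", "three_prime_utr")

_DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REPORT_GENE_COLUMN = "VEP_Ensembl_Gene_Name"
REPORT_COLUMNS = ("chr", "pos", "ref", "alt", REPORT_GENE_COLUMN)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_DNA_COMPLEMENT)


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix so ``chr3`` and ``3`` compare equal."""
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


def _chrom_sort_key(label: str):
    c = normalize_chrom(label)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant in 1-based plus-strand genomic coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not an SNV: {self.ref}>{self.alt}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"alleles must be A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    def with_gene(self, gene: str) -> "VariantRecord":
        return replace(self, gene=gene)

    @property
    def key(self) -> tuple:
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)

    def sort_key(self) -> tuple:
        return (_chrom_sort_key(self.chrom), self.pos, self.alt)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's annotated regions (5'UTR / CDS / 3'UTR) on one chromosome.

    ``regions`` holds ``(region_kind, start, end)`` triples, 1-based inclusive.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    regions: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        by_kind: dict[str, list[tuple[int, int]]] = {}
        for kind, start, end in self.regions:
            if kind not in REGION_KINDS:
                raise ValueError(
                    f"unknown region kind {kind!r} in transcript {self.transcript_id}"
                )
            if start > end:
                raise ValueError(
                    f"interval start > end ({start} > {end}) in {self.transcript_id}"
                )
            by_kind.setdefault(kind, []).append((start, end))
        for kind, ivals in by_kind.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping {kind} intervals in {self.transcript_id}: "
                        f"[{s1},{e1}] and [{s2},{e2}]"
                    )

    def footprint(self) -> tuple[int, int]:
        starts = [s for _, s, _ in self.regions]
        ends = [e for _, _, e in self.regions]
        return min(starts), max(ends)

    def region_kinds_at(self, pos: int) -> list[str]:
        return [k for k, s, e in self.regions if s <= pos <= e]


@dataclass(frozen=True)
class UTRSequence:
    """A transcript's 3'UTR as an mRNA-sense DNA string with its genomic span."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    genomic_span: tuple[tuple[int, int], ...]
    sequence: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        span_len = sum(e - s + 1 for s, e in self.genomic_span)
        if span_len != len(self.sequence):
            raise ValueError(
                f"{self.transcript_id}: span length {span_len} != sequence "
                f"length {len(self.sequence)}"
            )
        if not set(self.sequence) <= set("ACGTN"):
            raise ValueError(f"{self.transcript_id}: sequence has non-ACGTN characters")

    def __len__(self) -> int:
        return len(self.sequence)

    def genomic_to_offset(self, pos: int) -> int | None:
        """Map a genomic position to a 1-based offset in the mRNA-sense sequence.

        Returns None when the position falls outside the span.  On the minus
        strand the transcript runs from high to low genomic coordinates.
        """
        spans = sorted(self.genomic_span)
        if self.strand == "+":
            consumed = 0
            for s, e in spans:
                if s <= pos <= e:
                    return consumed + (pos - s + 1)
                consumed += e - s + 1
        else:
            consumed = 0
            for s, e in reversed(spans):
                if s <= pos <= e:
                    return consumed + (e - pos + 1)
                consumed += e - s + 1
        return None

    def offset_to_genomic(self, offset: int) -> int:
        if not 1 <= offset <= len(self):
            raise ValueError(f"offset {offset} outside sequence of length {len(self)}")
        spans = sorted(self.genomic_span)
        remaining = offset
        if self.strand == "+":
            for s, e in spans:
                width = e - s + 1
                if remaining <= width:
                    return s + remaining - 1
                remaining -= width
        else:
            for s, e in reversed(spans):
                width = e - s + 1
                if remaining <= width:
                    return e - remaining + 1
                remaining -= width
        raise AssertionError("unreachable")

    def with_sequence(self, sequence: str) -> "UTRSequence":
        return replace(self, sequence=sequence)


@dataclass
class ExpressionMatrix:
    """Gene x tissue non-negative expression values (TPM-like) with brain flags."""

    values: pd.DataFrame                 # genes as index, tissues as columns
    brain_tissues: tuple[str, ...] = ()  # subset of columns flagged as brain

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.brain_tissues) - set(self.values.columns)
        if missing:
            raise ValueError(f"brain flags name unknown tissues: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read SNVs from a VCF 4.x file, one record per ALT allele.

    Multi-allelic rows are split; indel/MNV alleles are skipped with a
    warning.  Positions are kept 1-based as in the file.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    try:
        for i, v in enumerate(vcf, start=1):
            ref = v.REF.upper()
            for alt in v.ALT:
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES \
                        or alt not in NUCLEOTIDES:
                    log.warning(
                        "skipping non-SNV allele %s>%s at %s:%d (record %d)",
                        ref, alt, v.CHROM, v.POS, i,
                    )
                    continue
                records.append(VariantRecord(chrom=str(v.CHROM), pos=v.POS,
                                             ref=ref, alt=alt))
    except Exception as exc:  # cyvcf2 parse failures carry no position info
        raise ValueError(f"malformed VCF row in {path} after record "
                         f"{len(records)}: {exc}") from exc
    finally:
        vcf.close()
    return records


def write_vcf(records: Sequence[VariantRecord], path: str | Path,
              seed: int | None = None) -> None:
    """Write SNVs as a minimal VCF 4.2 file (sorted by chrom, pos, alt)."""
    recs = sorted(records, key=VariantRecord.sort_key)
    chroms = []
    for r in recs:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if seed is not None:
            fh.write(f"##seedshift_generator_seed={seed}\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in recs:
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------

_GTF_KIND = {"five_prime_utr": "five_prime_utr", "cds": "cds",
             "three_prime_utr": "three_prime_utr"}

BED_TSV_COLUMNS = ("chrom", "start", "end", "transcript_id", "gene_symbol",
                   "strand", "region_kind")


def read_transcript_models(path: str | Path, dialect: str = "bed_tsv"
                           ) -> list[TranscriptModel]:
    """Read transcript region models from GTF or a BED-like TSV.

    GTF intervals are 1-based inclusive; the BED-like TSV is 0-based
    half-open.  Both are normalized to internal 1-based inclusive.
    """
    if dialect == "gtf":
        rows = _read_models_gtf(path)
    elif dialect == "bed_tsv":
        rows = _read_models_bed_tsv(path)
    else:
        raise ValueError(f"unknown transcript-model dialect {dialect!r}")

    grouped: dict[str, dict] = {}
    for tid, gene, chrom, strand, kind, start, end in rows:
        if start > end:
            raise ValueError(f"interval start > end in transcript {tid}: "
                             f"[{start},{end}]")
        g = grouped.setdefault(tid, {"gene": gene, "chrom": chrom,
                                     "strand": strand, "regions": []})
        if g["chrom"] != chrom:
            raise ValueError(f"transcript {tid} spans chromosomes "
                             f"{g['chrom']} and {chrom}")
        if g["strand"] != strand:
            raise ValueError(f"transcript {tid} has inconsistent strand")
        g["regions"].append((kind, start, end))

    return [
        TranscriptModel(transcript_id=tid, gene_symbol=g["gene"],
                        chrom=g["chrom"], strand=g["strand"],
                        regions=tuple(sorted(g["regions"],
                                             key=lambda r: (r[1], r[2], r[0]))))
        for tid, g in sorted(grouped.items())
    ]


def _read_models_gtf(path):
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    rows = []
    for feat in db.all_features():
        kind = feat.featuretype.lower()
        if kind not in _GTF_KIND:
            if kind in ("gene", "transcript", "exon", "start_codon",
                        "stop_codon"):
                continue
            raise ValueError(f"unknown region kind {feat.featuretype!r} in GTF")
        tid = feat.attributes["transcript_id"][0]
        gene = (feat.attributes.get("gene_name") or
                feat.attributes.get("gene_id"))[0]
        rows.append((tid, gene, str(feat.seqid), feat.strand,
                     _GTF_KIND[kind], feat.start, feat.end))
    return rows


def _read_models_bed_tsv(path):
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=BED_TSV_COLUMNS, dtype={"chrom": str})
    rows = []
    for r in df.itertuples(index=False):
        kind = str(r.region_kind)
        if kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {kind!r} in {path}")
        # 0-based half-open -> 1-based inclusive
        rows.append((str(r.transcript_id), str(r.gene_symbol), str(r.chrom),
                     str(r.strand), kind, int(r.start) + 1, int(r.end)))
    return rows


def write_transcript_models(models: Sequence[TranscriptModel],
                            path: str | Path, seed: int | None = None) -> None:
    """Write transcript models as the BED-like TSV dialect (0-based half-open)."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seedshift generator seed={seed}\n")
        fh.write("# " + "\t".join(BED_TSV_COLUMNS) + "\n")
        for m in models:
            for kind, start, end in m.regions:
                fh.write(f"{m.chrom}\t{start - 1}\t{end}\t{m.transcript_id}\t"
                         f"{m.gene_symbol}\t{m.strand}\t{kind}\n")


# ---------------------------------------------------------------------------
# FASTA: 3'UTR sequences and mature miRNAs
# ---------------------------------------------------------------------------

def read_utr_fasta(path: str | Path) -> list[UTRSequence]:
    """Read 3'UTR sequences whose headers carry gene/chrom/strand/span tokens.

    Header layout: ``>TRANSCRIPT gene=SYM chrom=3 strand=+ span=100-200,300-400``
    """
    utrs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(t.split("=", 1) for t in rec.description.split()[1:]
                      if "=" in t)
        for required in ("gene", "chrom", "strand", "span"):
            if required not in tokens:
                raise ValueError(f"UTR FASTA header for {rec.id} lacks "
                                 f"'{required}=' token")
        span = tuple(
            (int(a), int(b))
            for a, b in (part.split("-") for part in tokens["span"].split(","))
        )
        utrs.append(UTRSequence(
            transcript_id=rec.id, gene_symbol=tokens["gene"],
            chrom=tokens["chrom"], strand=tokens["strand"],
            genomic_span=span, sequence=str(rec.seq).upper().replace("U", "T"),
        ))
    return utrs


def write_utr_fasta(utrs: Sequence[UTRSequence], path: str | Path,
                    seed: int | None = None) -> None:
    records = []
    for u in utrs:
        span = ",".join(f"{s}-{e}" for s, e in u.genomic_span)
        desc = f"gene={u.gene_symbol} chrom={u.chrom} strand={u.strand} span={span}"
        if seed is not None:
            desc += f" seed={seed}"
        records.append(SeqRecord(Seq(u.sequence), id=u.transcript_id,
                                 description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_mirna_fasta(path: str | Path) -> dict[str, str]:
    """Read a miRBase-dialect mature miRNA FASTA into {name: RNA sequence}.

    The name is the first header token (e.g. ``hsa-miR-137-3p``); sequences
    are returned uppercase RNA (T converted to U).
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        if rec.id in out and out[rec.id] != seq:
            raise ValueError(f"conflicting sequences for miRNA {rec.id}")
        out[rec.id] = seq
    return out


def write_mirna_fasta(mirnas: Mapping[str, str], path: str | Path,
                      seed: int | None = None) -> None:
    records = []
    for i, (name, seq) in enumerate(mirnas.items()):
        desc = f"MIMAT{900000 + i:07d} Homo sapiens {name.removeprefix('hsa-')}"
        if seed is not None:
            desc += f" seed={seed}"
        records.append(SeqRecord(Seq(seq.upper().replace("T", "U")), id=name,
                                 description=desc))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Expression TSV (+ brain-flag sidecar)
# ---------------------------------------------------------------------------

def read_expression(path: str | Path,
                    brain_flags_path: str | Path | None = None
                    ) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    brain: tuple[str, ...] = ()
    if brain_flags_path is not None:
        flags = pd.read_csv(brain_flags_path, sep="\t", comment="#")
        flags.columns = [c.lower() for c in flags.columns]
        brain = tuple(flags.loc[flags["is_brain"].astype(bool), "tissue"])
    return ExpressionMatrix(values=values.astype(float), brain_tissues=brain)


def write_expression(m: ExpressionMatrix, path: str | Path,
                     brain_flags_path: str | Path | None = None,
                     seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seedshift generator seed={seed}\n")
        m.values.to_csv(fh, sep="\t", float_format="%.6f", index_label="gene")
    if brain_flags_path is not None:
        with open(brain_flags_path, "w") as fh:
            if seed is not None:
                fh.write(f"# seedshift generator seed={seed}\n")
            fh.write("tissue\tis_brain\n")
            for t in m.tissues:
                fh.write(f"{t}\t{int(t in m.brain_tissues)}\n")


# ---------------------------------------------------------------------------
# Variant report (Table-style TSV)
# ---------------------------------------------------------------------------

def write_report(records: Sequence[VariantRecord], path: str | Path,
                 annotations: Sequence[Mapping[str, object]] | None = None
                 ) -> None:
    """Write the variant report TSV, sorted by (chrom, pos, alt).

    Every record must carry a gene symbol; ``annotations`` (parallel to
    ``records``) adds extra columns after the five fixed ones.
    """
    if annotations is not None and len(annotations) != len(records):
        raise ValueError("annotations must parallel records")
    for r in records:
        if not r.gene:
            raise ValueError(f"unannotated record (no gene) at {r.chrom}:{r.pos}")

    extra_cols: list[str] = []
    if annotations:
        for ann in annotations:
            for k in ann:
                if k not in extra_cols:
                    extra_cols.append(k)

    paired = list(zip(records, annotations or [{} for _ in records]))
    paired.sort(key=lambda p: p[0].sort_key())
    with open(path, "w") as fh:
        fh.write("\t".join(list(REPORT_COLUMNS) + extra_cols) + "\n")
        for r, ann in paired:
            row = [str(r.chrom), str(r.pos), r.ref, r.alt, r.gene]
            row += [str(ann.get(c, "")) for c in extra_cols]
            fh.write("\t".join(row) + "\n")


def read_report(path: str | Path) -> list[VariantRecord]:
    """Read a report TSV back into variant records (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report {path} lacks columns {sorted(missing)}")
    return [
        VariantRecord(chrom=str(r["chr"]), pos=int(r["pos"]), ref=str(r["ref"]),
                      alt=str(r["alt"]), gene=str(r[REPORT_GENE_COLUMN]))
        for _, r in df.iterrows()
    ]


def load_curated_variants() -> list[VariantRecord]:
    """The bundled set of 22 curated 3'UTR SNVs altering miRNA target sites.

    These variants fall in the 3'UTRs of GPR88, WNT7A and CDK6 — three genes
    targeted by miR-137 and linked to intellectual disability — and were the
    exclusively-3'UTR hits of a literature-curated miRNA--mRNA pair screen.
    """
    ref = resources.files("seedshift").joinpath("data/id_utr_variants.tsv")
    with resources.as_file(ref) as p:
        return read_report(p)
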