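"""Synthetic input bundles with planted, self-verified ground truth.

The generator emulates every input the pipeline consumes — curated pairs,
alias tables, a mature miRNA FASTA, multi-isoform transcript models, 3'UTR
FASTA, a VCF of SNVs and a GTEx-like tissue expression matrix — with known
planted events:

* loss / gain / substitution / none variants placed where every isoform is
  3'UTR (they survive the exclusivity filter);
* additional variants placed where a secondary isoform's CDS extends into
  the primary 3'UTR (they are dropped by the filter);
* brain-enriched genes whose brain/non-brain mean expression ratio is a
  configurable rho, under multiplicative lognormal noise.

Background sequence is i.i.d. with configurable GC.  Every planted variant
is re-checked at generation time against a brute-force base-pairing scan of
the full emitted miRNA library (independent of the production seed
matcher); an event whose classification would disagree with its label is
re-planted at a fresh location until it verifies, so the emitted ground
truth is exact by construction.  Identical seeds yield byte-identical
bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .expression import DEFAULT_BRAIN_TISSUES
from .io_formats import (ExpressionMatrix, TranscriptModel, UTRSequence,
                         VariantRecord, complement_base)

log = logging.getLogger(__name__)

_NON_BRAIN_TISSUES = (
    "Adipose - Subcutaneous", "Adipose - Visceral (Omentum)", "Adrenal Gland",
    "Artery - Aorta", "Artery - Coronary", "Artery - Tibial", "Bladder",
    "Breast - Mammary Tissue", "Cells - EBV-transformed lymphocytes",
    "Cells - Transformed fibroblasts", "Cervix - Ectocervix",
    "Cervix - Endocervix", "Colon - Sigmoid", "Colon - Transverse",
    "Esophagus - Gastroesophageal Junction", "Esophagus - Mucosa",
    "Esophagus - Muscularis", "Fallopian Tube", "Heart - Atrial Appendage",
    "Heart - Left Ventricle", "Kidney - Cortex", "Liver", "Lung",
    "Minor Salivary Gland", "Muscle - Skeletal", "Nerve - Tibial", "Ovary",
    "Pancreas", "Pituitary", "Prostate",
    "Skin - Not Sun Exposed (Suprapubic)", "Skin - Sun Exposed (Lower leg)",
    "Small Intestine - Terminal Ileum", "Spleen", "Stomach", "Testis",
    "Thyroid", "Uterus", "Vagina", "Whole Blood",
)

# DNA (target) base paired with RNA (miRNA) base, Watson-Crick only
_PAIRS = {("A", "U"), ("C", "G"), ("G", "C"), ("T", "A")}

_RNA_FROM_DNA_COMPLEMENT = str.maketrans("ACGT", "UGCA")
_DNA_FROM_RNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")


@dataclass
class GeneratorConfig:
    """Study-shaped defaults: ~100 curated pairs over ~20 genes with 2-4
    isoforms each, 0.3-3 kb UTRs, and 53 tissues of which 13 are brain."""

    n_loss: int = 10
    n_gain: int = 5
    n_substitution: int = 4
    n_none: int = 5
    n_nonexclusive: int = 3
    n_genes: int = 20
    n_mirnas: int = 30
    n_pairs: int = 100
    n_unresolved_pairs: int = 2
    isoforms_min: int = 2
    isoforms_max: int = 4
    utr_len_min: int = 300
    utr_len_max: int = 3000
    gc_content: float = 0.45
    rho: float = 10.0
    noise_sd: float = 0.25
    n_brain_genes: int = 3
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_loss, self.n_gain, self.n_substitution, self.n_none,
                  self.n_nonexclusive, self.n_genes, self.n_mirnas,
                  self.n_pairs)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.utr_len_min < 150:
            raise ValueError("UTRs shorter than 150 nt cannot host planted "
                             "sites with isoform overlap zones")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# seedshift generator configuration\n")
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown generator config key {key!r}")
            caster = float if key in ("gc_content", "rho", "noise_sd") else int
            kwargs[key] = caster(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class PlantedEvent:
    variant: VariantRecord
    gene: str
    paired_mirna: str
    classification: str
    exclusive: bool


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream recovery checks."""

    planted_events: list[PlantedEvent]
    planted_exclusive: list[VariantRecord]
    brain_genes: dict[str, float]  # gene -> planted brain/non-brain ratio
    noise_sd: float
    seed: int

    def expected_tally(self) -> dict[str, int]:
        """Classification counts over the exclusivity-surviving events."""
        tally = {"loss": 0, "gain": 0, "substitution": 0, "none": 0}
        for ev in self.planted_events:
            if ev.exclusive:
                tally[ev.classification] += 1
        return tally

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "brain_genes": self.brain_genes,
            "expected_tally": self.expected_tally(),
            "planted_events": [
                {"chrom": e.variant.chrom, "pos": e.variant.pos,
                 "ref": e.variant.ref, "alt": e.variant.alt, "gene": e.gene,
                 "paired_mirna": e.paired_mirna,
                 "classification": e.classification,
                 "exclusive": e.exclusive}
                for e in self.planted_events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        events = [
            PlantedEvent(
                variant=VariantRecord(chrom=e["chrom"], pos=e["pos"],
                                      ref=e["ref"], alt=e["alt"],
                                      gene=e["gene"]),
                gene=e["gene"], paired_mirna=e["paired_mirna"],
                classification=e["classification"], exclusive=e["exclusive"])
            for e in payload["planted_events"]
        ]
        return cls(planted_events=events,
                   planted_exclusive=[e.variant for e in events if e.exclusive],
                   brain_genes=payload["brain_genes"],
                   noise_sd=payload["noise_sd"], seed=payload["seed"])


# ---------------------------------------------------------------------------
# brute-force verification oracle (base-pairing walk, no site strings)
# ---------------------------------------------------------------------------

def _bf_site_overlaps(seq: str, mir: str, off0: int) -> bool:
    """True iff any canonical seed site of ``mir`` covers 0-based ``off0``.

    Checks every candidate window by direct Watson-Crick pairing of target
    bases against miRNA seed positions, independently of the production
    site-string construction.
    """
    L = len(seq)

    def paired(k_target: int, pos_mirna: int) -> bool:
        return (seq[k_target], mir[pos_mirna - 1]) in _PAIRS

    for i in range(max(0, off0 - 7), off0 + 1):
        # 8mer: target i..i+7 pairs miRNA 8..2, plus A opposite position 1
        if i + 8 <= L and off0 <= i + 7 and seq[i + 7] == "A" \
                and all(paired(i + k, 8 - k) for k in range(7)):
            return True
        # 7mer-m8: target i..i+6 pairs miRNA 8..2
        if i + 7 <= L and off0 <= i + 6 \
                and all(paired(i + k, 8 - k) for k in range(7)):
            return True
        # 7mer-A1: target i..i+5 pairs miRNA 7..2, plus A opposite position 1
        if i + 7 <= L and off0 <= i + 6 and seq[i + 6] == "A" \
                and all(paired(i + k, 7 - k) for k in range(6)):
            return True
        # 6mer: target i..i+5 pairs miRNA 7..2
        if i + 6 <= L and off0 <= i + 5 \
                and all(paired(i + k, 7 - k) for k in range(6)):
            return True
    return False


def _bf_classify(ref_seq: str, alt_seq: str, off0: int, paired_name: str,
                 library: dict[str, str]) -> str:
    paired_ref = paired_alt = False
    gained = []
    for name in sorted(library):
        on_ref = _bf_site_overlaps(ref_seq, library[name], off0)
        on_alt = _bf_site_overlaps(alt_seq, library[name], off0)
        if name == paired_name:
            paired_ref, paired_alt = on_ref, on_alt
        if on_alt and not on_ref:
            gained.append(name)
    others = [g for g in gained if g != paired_name]
    if paired_ref and not paired_alt:
        return "substitution" if others else "loss"
    if not paired_ref and gained:
        return "gain"
    return "none"


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))

def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


def _site_8mer(mir: str) -> str:
    """mRNA-sense DNA 8mer site for an RNA miRNA (revcomp of 2-8, plus A)."""
    return mir[1:8].translate(_DNA_FROM_RNA_COMPLEMENT)[::-1] + "A"


def _mirna_from_7mer_site(rng: np.random.Generator, site7: str) -> str:
    """Craft an RNA miRNA whose 7mer-m8 target string equals ``site7``."""
    seed28 = site7.translate(_RNA_FROM_DNA_COMPLEMENT)[::-1]  # positions 2-8
    return _random_rna(rng, 1) + seed28 + _random_rna(rng, 13)


@dataclass
class _Gene:
    symbol: str
    gene_id: str
    chrom: str
    strand: str
    utr_len: int
    ext: int                   # CDS extension of secondary isoforms (nt)
    n_isoforms: int
    utr_g_start: int = 0       # genomic start of the primary 3'UTR
    utr_g_end: int = 0
    seq: list[str] = field(default_factory=list)  # mRNA-sense, 0-based
    paired_mirna: str = ""


@dataclass
class _Event:
    gene: _Gene
    kind: str          # intended classification
    exclusive: bool
    site_start: int = -1   # 0-based index of the 8-nt planting window
    var_off: int = -1      # 0-based UTR offset of the variant
    ref_base: str = ""     # mRNA-sense alleles
    alt_base: str = ""
    gain_mirna: str = ""       # for gain events
    crafted_mirna: str = ""    # for substitution events
    crafted_j: int = -1        # variant index within the site (substitution)
    crafted_alt: str = ""


_RESERVE_LEFT, _RESERVE_RIGHT = 10, 17  # reserved window around a site start


def generate(config: GeneratorConfig, outdir: str | Path
             ) -> tuple[dict[str, Path], GroundTruth]:
    """Emit a full input bundle into ``outdir``; returns paths and truth.

    Raises RuntimeError if a planted event cannot be made to verify against
    the brute-force oracle (an impossible configuration).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- miRNA library -----------------------------------------------------
    library: dict[str, str] = {}
    for i in range(config.n_mirnas):
        arm = "5p" if i % 2 == 0 else "3p"
        name = f"hsa-miR-{300 + i}-{arm}"
        library[name] = _random_rna(rng, int(rng.integers(20, 23)))

    # --- genes and isoform structure --------------------------------------
    genes: list[_Gene] = []
    mirna_names = list(library)
    for i in range(config.n_genes):
        utr_len = int(rng.integers(config.utr_len_min, config.utr_len_max + 1))
        ext = min(max(100, utr_len // 4), utr_len - 150)
        g = _Gene(symbol=f"IDG{i + 1:03d}", gene_id=f"SYNG{i + 1:011d}",
                  chrom=str(i + 1), strand="+" if i % 2 == 0 else "-",
                  utr_len=utr_len, ext=ext,
                  n_isoforms=int(rng.integers(config.isoforms_min,
                                              config.isoforms_max + 1)))
        g.paired_mirna = mirna_names[i % len(mirna_names)]
        g.seq = _random_dna(rng, utr_len, config.gc_content)
        if g.strand == "+":
            g.utr_g_start, g.utr_g_end = 2101, 2100 + utr_len
        else:
            g.utr_g_start, g.utr_g_end = 1001, 1000 + utr_len
        genes.append(g)

    # --- plan events (round-robin over genes) ------------------------------
    events: list[_Event] = []
    kinds = (["loss"] * config.n_loss + ["gain"] * config.n_gain +
             ["substitution"] * config.n_substitution +
             ["none"] * config.n_none)
    for k, kind in enumerate(kinds):
        events.append(_Event(gene=genes[k % len(genes)], kind=kind,
                             exclusive=True))
    for k in range(config.n_nonexclusive):
        events.append(_Event(gene=genes[k % len(genes)], kind="loss",
                             exclusive=False))

    # craft substitution partner miRNAs up front so the library is complete
    # before any placement is verified
    for idx, ev in enumerate(e for e in events if e.kind == "substitution"):
        site8 = _site_8mer(library[ev.gene.paired_mirna])
        j = int(rng.integers(1, 7))  # within the seed-critical span
        alt = str(rng.choice([b for b in "ACGT" if b != site8[j]]))
        broken7 = (site8[:j] + alt + site8[j + 1:])[:7]
        name = f"hsa-miR-{9000 + idx}-3p"
        library[name] = _mirna_from_7mer_site(rng, broken7)
        ev.crafted_mirna, ev.crafted_j, ev.crafted_alt = name, j, alt

    # --- place and verify events -------------------------------------------
    reserved: dict[str, list[tuple[int, int]]] = {g.symbol: [] for g in genes}

    def _zone(ev: _Event) -> tuple[int, int]:
        g = ev.gene
        return (0, g.ext - 1) if not ev.exclusive else (g.ext, g.utr_len - 1)

    def _pick_site_start(ev: _Event) -> int:
        lo, hi = _zone(ev)
        lo_i, hi_i = lo + _RESERVE_LEFT, hi - _RESERVE_RIGHT
        if hi_i < lo_i:
            raise RuntimeError(f"gene {ev.gene.symbol}: zone too small for a "
                               "planted site")
        for _ in range(500):
            i = int(rng.integers(lo_i, hi_i + 1))
            window = (i - _RESERVE_LEFT, i + _RESERVE_RIGHT)
            if all(window[1] < s or window[0] > e
                   for s, e in reserved[ev.gene.symbol]):
                return i
        raise RuntimeError(f"gene {ev.gene.symbol}: could not reserve a "
                           "planting window (UTR too crowded)")

    def _plant(ev: _Event, fresh_location: bool) -> None:
        g = ev.gene
        if fresh_location:
            old = (ev.site_start - _RESERVE_LEFT,
                   ev.site_start + _RESERVE_RIGHT)
            if ev.site_start >= 0 and old in reserved[g.symbol]:
                reserved[g.symbol].remove(old)
            ev.site_start = _pick_site_start(ev)
            reserved[g.symbol].append((ev.site_start - _RESERVE_LEFT,
                                       ev.site_start + _RESERVE_RIGHT))
        i = ev.site_start
        # refresh the reserved window with new background
        lo, hi = i - _RESERVE_LEFT, i + _RESERVE_RIGHT
        g.seq[lo:hi + 1] = _random_dna(rng, hi - lo + 1, config.gc_content)

        if ev.kind in ("loss",):
            site8 = _site_8mer(library[g.paired_mirna])
            g.seq[i:i + 8] = list(site8)
            j = int(rng.integers(1, 7))
            ev.var_off = i + j
            ev.ref_base = site8[j]
            ev.alt_base = str(rng.choice([b for b in "ACGT" if b != site8[j]]))
        elif ev.kind == "gain":
            ev.gain_mirna = str(rng.choice(sorted(library)))
            site8 = _site_8mer(library[ev.gain_mirna])
            j = int(rng.integers(1, 7))
            broken = str(rng.choice([b for b in "ACGT" if b != site8[j]]))
            planted = site8[:j] + broken + site8[j + 1:]
            g.seq[i:i + 8] = list(planted)
            ev.var_off = i + j
            ev.ref_base, ev.alt_base = broken, site8[j]
        elif ev.kind == "substitution":
            site8 = _site_8mer(library[g.paired_mirna])
            g.seq[i:i + 8] = list(site8)
            ev.var_off = i + ev.crafted_j
            ev.ref_base = site8[ev.crafted_j]
            ev.alt_base = ev.crafted_alt
        elif ev.kind == "none":
            ev.var_off = i + 4
            ev.ref_base = g.seq[ev.var_off]
            ev.alt_base = str(rng.choice([b for b in "ACGT"
                                          if b != ev.ref_base]))
        else:  # pragma: no cover
            raise AssertionError(ev.kind)

    def _verifies(ev: _Event) -> bool:
        g = ev.gene
        ref = "".join(g.seq)
        alt = ref[:ev.var_off] + ev.alt_base + ref[ev.var_off + 1:]
        return _bf_classify(ref, alt, ev.var_off, g.paired_mirna,
                            library) == ev.kind

    for ev in events:
        _plant(ev, fresh_location=True)

    # iterate until the whole bundle self-verifies: the generator refuses to
    # emit planted labels that disagree with the brute-force oracle
    for _round in range(200):
        bad = [ev for ev in events if not _verifies(ev)]
        if not bad:
            break
        for ev in bad:
            _plant(ev, fresh_location=True)
    else:
        raise RuntimeError("planted events failed to verify after 200 rounds")

    # --- assemble variants, models, UTRs -----------------------------------
    planted: list[PlantedEvent] = []
    for ev in events:
        g = ev.gene
        if g.strand == "+":
            pos = g.utr_g_start + ev.var_off
            ref, alt = ev.ref_base, ev.alt_base
        else:
            pos = g.utr_g_end - ev.var_off
            ref = complement_base(ev.ref_base)
            alt = complement_base(ev.alt_base)
        planted.append(PlantedEvent(
            variant=VariantRecord(chrom=g.chrom, pos=pos, ref=ref, alt=alt,
                                  gene=g.symbol),
            gene=g.symbol, paired_mirna=g.paired_mirna,
            classification=ev.kind, exclusive=ev.exclusive))

    models: list[TranscriptModel] = []
    utrs: list[UTRSequence] = []
    for g in genes:
        L, ext = g.utr_len, g.ext
        for k in range(g.n_isoforms):
            tid = f"{g.symbol}-T{k + 1}"
            e_k = 0 if k == 0 else ext  # secondary isoforms extend the CDS
            if g.strand == "+":
                utr_iv = (g.utr_g_start + e_k, g.utr_g_end)
                cds_iv = (1201, 2100 + e_k)
                utr5_iv = (1001, 1200)
            else:
                utr_iv = (g.utr_g_start, g.utr_g_end - e_k)
                cds_iv = (g.utr_g_end - e_k + 1, g.utr_g_end + 900)
                utr5_iv = (g.utr_g_end + 901, g.utr_g_end + 1100)
            models.append(TranscriptModel(
                transcript_id=tid, gene_symbol=g.symbol, chrom=g.chrom,
                strand=g.strand,
                regions=(("five_prime_utr",) + utr5_iv,
                         ("cds",) + cds_iv,
                         ("three_prime_utr",) + utr_iv)))
            utrs.append(UTRSequence(
                transcript_id=tid, gene_symbol=g.symbol, chrom=g.chrom,
                strand=g.strand, genomic_span=(utr_iv,),
                sequence="".join(g.seq[e_k:])))

    # --- curated pairs and alias table -------------------------------------
    pair_rows: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for g in genes:
        pair_rows.append((g.paired_mirna, g.symbol, "planted"))
        seen.add((g.paired_mirna, g.symbol))
    filler = 0
    while len(pair_rows) < config.n_pairs:
        m = str(rng.choice(mirna_names))
        g = genes[int(rng.integers(len(genes)))]
        if (m, g.symbol) in seen:
            continue
        seen.add((m, g.symbol))
        filler += 1
        # exercise the normalizers: precursor spellings and gene aliases
        m_out = m
        g_out = g.symbol
        if filler % 3 == 0:
            m_out = m.rsplit("-", 1)[0].replace("miR", "mir")  # precursor
        if filler % 4 == 0:
            g_out = f"{g.symbol}-alias1"
        pair_rows.append((m_out, g_out, "literature"))
    for u in range(config.n_unresolved_pairs):
        pair_rows.append((f"hsa-miR-{77000 + u}-5p", f"NO_SUCH_GENE{u + 1}",
                          "unresolvable"))

    alias_rows = [(g.symbol, g.symbol, g.gene_id) for g in genes]
    alias_rows += [(f"{g.symbol}-alias1", g.symbol, g.gene_id) for g in genes]

    # --- expression matrix --------------------------------------------------
    tissues = list(DEFAULT_BRAIN_TISSUES) + list(_NON_BRAIN_TISSUES)
    brain_genes = {g.symbol: config.rho
                   for g in genes[:config.n_brain_genes]}
    rows = []
    for g in genes:
        base = float(rng.uniform(5.0, 50.0))
        rho = brain_genes.get(g.symbol, 1.0)
        noise = np.exp(rng.normal(0.0, config.noise_sd, size=len(tissues)))
        mean = np.array([base * rho if t in DEFAULT_BRAIN_TISSUES else base
                         for t in tissues])
        rows.append(mean * noise)
    expr = ExpressionMatrix(
        values=pd.DataFrame(rows, index=[g.symbol for g in genes],
                            columns=tissues),
        brain_tissues=tuple(DEFAULT_BRAIN_TISSUES))

    # --- emit ----------------------------------------------------------------
    seed = config.seed
    paths = {
        "mirna_fasta": outdir / "mature_mirnas.fa",
        "utr_fasta": outdir / "utr_sequences.fa",
        "models": outdir / "transcript_models.tsv",
        "vcf": outdir / "variants.vcf",
        "pairs": outdir / "pairs.tsv",
        "aliases": outdir / "gene_aliases.tsv",
        "expression": outdir / "expression.tsv",
        "brain_flags": outdir / "brain_tissues.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "generator_config.txt",
    }
    io_formats.write_mirna_fasta(library, paths["mirna_fasta"], seed=seed)
    io_formats.write_utr_fasta(utrs, paths["utr_fasta"], seed=seed)
    io_formats.write_transcript_models(models, paths["models"], seed=seed)
    io_formats.write_vcf([e.variant for e in planted], paths["vcf"], seed=seed)
    with open(paths["pairs"], "w") as fh:
        fh.write(f"# seedshift generator seed={seed}\n")
        fh.write("mirna\tgene\tsource\n")
        for m, g_sym, src in pair_rows:
            fh.write(f"{m}\t{g_sym}\t{src}\n")
    with open(paths["aliases"], "w") as fh:
        fh.write(f"# seedshift generator seed={seed}\n")
        fh.write("alias\tofficial\tgene_id\n")
        for a, o, gid in alias_rows:
            fh.write(f"{a}\t{o}\t{gid}\n")
    io_formats.write_expression(expr, paths["expression"],
                                brain_flags_path=paths["brain_flags"],
                                seed=seed)
    truth = GroundTruth(
        planted_events=planted,
        planted_exclusive=[e.variant for e in planted if e.exclusive],
        brain_genes=brain_genes, noise_sd=config.noise_sd, seed=seed)
    truth.to_json(paths["ground_truth"])
    config.to_file(paths["config"])
    return paths, truth
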