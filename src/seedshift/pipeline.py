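"""End-to-end orchestration of the 3'UTR variant prioritization workflow.

Stages run in order: name normalization -> allele-aware seed scanning and
classification -> isoform 3'UTR-exclusivity filter -> classification tally
-> expression normalization and brain-enrichment ranking -> conservation
windows and the motif presence test.  Every stage writes its table to the
output directory and its input/output counts to a machine-readable run
summary, so the variant funnel is auditable and stages can be re-examined
independently.  Runs are deterministic: the same configuration yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io_formats, motif_stats, nomenclature, region_filter
from . import expression as expr_mod
from . import target_scan

log = logging.getLogger(__name__)

_FISHER_MODES = ("control", "iid")
_ARM_POLICIES = ("both", "5p", "3p")
_DIALECTS = ("bed_tsv", "gtf")


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run; round-trips through a flat
    key=value file."""

    pairs: str
    aliases: str
    mirna_fasta: str
    utr_fasta: str
    models: str
    vcf: str
    expression: str
    brain_flags: str
    outdir: str
    models_dialect: str = "bed_tsv"
    arm_policy: str = "both"
    fisher_mode: str = "control"
    motif: str = ""
    background_utr_fasta: str = ""
    window_width: int = 100
    pseudocount: float = 1.0
    seed: int = 0

    _PATH_FIELDS = ("pairs", "aliases", "mirna_fasta", "utr_fasta", "models",
                    "vcf", "expression", "brain_flags")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# seedshift run configuration\n")
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        casters = {"window_width": int, "seed": int, "pseudocount": float}
        names = {f.name for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in names:
                raise ValueError(f"unknown run config key {key!r}")
            kwargs[key] = casters.get(key, str)(value)
        return cls(**kwargs)


def validate(config: RunConfig) -> list[str]:
    """All detectable configuration problems, without running anything."""
    problems = []
    for name in RunConfig._PATH_FIELDS:
        p = getattr(config, name)
        if not p:
            problems.append(f"{name}: no path configured")
        elif not Path(p).is_file():
            problems.append(f"{name}: file not found: {p}")
    if config.background_utr_fasta and \
            not Path(config.background_utr_fasta).is_file():
        problems.append("background_utr_fasta: file not found: "
                        f"{config.background_utr_fasta}")
    if config.models_dialect not in _DIALECTS:
        problems.append(f"models_dialect: unknown dialect "
                        f"{config.models_dialect!r} (expected {_DIALECTS})")
    if config.arm_policy not in _ARM_POLICIES:
        problems.append(f"arm_policy: unknown policy {config.arm_policy!r}")
    if config.fisher_mode not in _FISHER_MODES:
        problems.append(f"fisher_mode: unknown mode {config.fisher_mode!r}")
    if config.fisher_mode == "control" and config.motif and \
            not config.background_utr_fasta:
        problems.append("fisher_mode 'control' with a motif requires "
                        "background_utr_fasta")
    if config.window_width < 1:
        problems.append("window_width must be >= 1")
    return problems


def _stage(summary: dict, name: str, **counts) -> None:
    summary["stages"][name] = counts
    log.info("stage %s: %s", name,
             ", ".join(f"{k}={v}" for k, v in counts.items()))


def run(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run summary dict.

    Any stage's hard error aborts the run with the stage name prepended to
    the message.
    """
    problems = validate(config)
    if problems:
        raise ValueError("invalid run configuration: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {},
                     "config": dataclasses.asdict(config)}

    def guarded(stage_name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {stage_name!r} failed: {exc}") from exc

    # ---- stage 1: nomenclature -------------------------------------------
    pairs = guarded("nomenclature", nomenclature.read_pairs, config.pairs)
    alias_table = guarded("nomenclature", nomenclature.load_alias_table,
                          config.aliases)
    mirna_seqs = guarded("nomenclature", io_formats.read_mirna_fasta,
                         config.mirna_fasta)
    name_map = nomenclature.build_mirna_name_map(mirna_seqs)
    resolved = guarded("nomenclature", nomenclature.resolve_pairs, pairs,
                       alias_table, name_map, config.arm_policy)
    ok_pairs = [r for r in resolved if r.resolved]
    pd.DataFrame([{
        "mirna_raw": r.pair.mirna_name_raw, "gene_raw": r.pair.gene_name_raw,
        "mature_mirnas": ",".join(r.mature_mirnas) or nomenclature.UNRESOLVED,
        "gene_symbol": r.gene_symbol, "gene_id": r.gene_id or "",
        "resolved": r.resolved, "source": r.pair.source,
    } for r in resolved]).to_csv(outdir / "resolved_pairs.tsv", sep="\t",
                                 index=False)
    _stage(summary, "nomenclature", pairs_in=len(pairs),
           resolved=len(ok_pairs), unresolved=len(resolved) - len(ok_pairs))
    if len(ok_pairs) + (len(resolved) - len(ok_pairs)) != len(pairs):
        raise RuntimeError("stage 'nomenclature': pair count not conserved")

    # ---- stage 2: allele-aware seed scan ----------------------------------
    variants = guarded("target_scan", io_formats.read_vcf, config.vcf)
    utrs = guarded("target_scan", io_formats.read_utr_fasta, config.utr_fasta)
    library = target_scan.build_library(mirna_seqs)

    # gene -> mature miRNA names paired with it by the curated list
    gene_pairs: dict[str, list[str]] = {}
    for r in ok_pairs:
        for m in r.mature_mirnas:
            gene_pairs.setdefault(r.gene_symbol, [])
            if m not in gene_pairs[r.gene_symbol]:
                gene_pairs[r.gene_symbol].append(m)

    def covering_utr(v):
        hits = [u for u in utrs
                if io_formats.normalize_chrom(u.chrom)
                == io_formats.normalize_chrom(v.chrom)
                and u.genomic_to_offset(v.pos) is not None]
        return min(hits, key=lambda u: u.transcript_id) if hits else None

    changes: list[target_scan.TargetChange] = []
    unmapped: list[io_formats.VariantRecord] = []
    for v in variants:
        u = covering_utr(v)
        if u is None:
            unmapped.append(v)
            continue
        for paired in gene_pairs.get(u.gene_symbol, []):
            changes.append(guarded(
                "target_scan", target_scan.classify_snv_effect, u, v, paired,
                library))
    _stage(summary, "target_scan", variants_in=len(variants),
           mapped=len(variants) - len(unmapped), unmapped=len(unmapped),
           classifications=len(changes))

    # ---- stage 3: isoform 3'UTR-exclusivity filter -------------------------
    models = guarded("region_filter", io_formats.read_transcript_models,
                     config.models, config.models_dialect)
    kept, dropped = guarded("region_filter", region_filter.filter_exclusive,
                            variants, models)
    audit = region_filter.audit_table(variants, models)
    audit.to_csv(outdir / "region_audit.tsv", sep="\t", index=False)
    if len(kept) + len(dropped) != len(variants):
        raise RuntimeError("stage 'region_filter': variant count not "
                           "conserved")
    _stage(summary, "region_filter", variants_in=len(variants),
           kept=len(kept), dropped=len(dropped))

    # ---- stage 4: report + tally on exclusivity-surviving variants ---------
    kept_keys = {v.key for v in kept}
    kept_changes = [c for c in changes if c.variant.key in kept_keys]
    records = [c.variant.with_gene(c.gene_symbol) for c in kept_changes]
    annotations = [{
        "paired_miRNA": c.paired_mirna, "classification": c.classification,
        "gained_miRNAs": ",".join(c.gained_mirnas),
        "ref_sites": ";".join(f"{s.mirna_name}:{s.site_type}@"
                              f"{s.utr_start}-{s.utr_end}"
                              for s in c.ref_sites),
        "alt_sites": ";".join(f"{s.mirna_name}:{s.site_type}@"
                              f"{s.utr_start}-{s.utr_end}"
                              for s in c.alt_sites),
    } for c in kept_changes]
    guarded("report", io_formats.write_report, records,
            outdir / "variant_report.tsv", annotations)
    per_pair = target_scan.tally_classifications(kept_changes)
    per_variant = target_scan.tally_variants(kept_changes)
    (outdir / "classification_tally.json").write_text(
        json.dumps({"per_pair": per_pair, "per_variant": per_variant},
                   indent=1) + "\n")
    _stage(summary, "tally", **per_variant)

    # ---- stage 5: expression ------------------------------------------------
    expr = guarded("expression", io_formats.read_expression,
                   config.expression, config.brain_flags)
    norm = guarded("expression", expr_mod.normalize_expression, expr,
                   config.pseudocount)
    io_formats.write_expression(norm, outdir / "normalized_expression.tsv")
    ranking = guarded("expression", expr_mod.brain_enrichment_rank, expr,
                      config.pseudocount)
    ranking.to_csv(outdir / "brain_enrichment.tsv", sep="\t",
                   index_label="gene", float_format="%.6f")
    _stage(summary, "expression", genes=len(expr.genes),
           tissues=len(expr.tissues), brain_tissues=len(expr.brain_tissues),
           top_brain_gene=(ranking.index[0] if len(ranking) else ""))

    # ---- stage 6: conservation windows + motif presence test ----------------
    windows = []
    for v in kept:
        u = covering_utr(v)
        if u is not None:
            windows.append(guarded("motif_stats", motif_stats.extract_window,
                                   u, v, config.window_width))
    motif_stats.write_windows_fasta(windows, outdir / "variant_windows.fa")
    motif_summary: dict = {"windows": len(windows)}
    if config.motif:
        background = None
        if config.fisher_mode == "control":
            background = guarded("motif_stats", io_formats.read_utr_fasta,
                                 config.background_utr_fasta)
        result = guarded("motif_stats", motif_stats.motif_presence_test,
                         config.motif, utrs, background)
        pd.DataFrame([dataclasses.asdict(result)]).to_csv(
            outdir / "motif_test.tsv", sep="\t", index=False)
        motif_summary.update(motif=result.motif, n_present=result.n_present,
                             n_total=result.n_total, p_value=result.p_value,
                             mode=result.mode)
    _stage(summary, "motif_stats", **motif_summary)

    (outdir / "run_summary.json").write_text(
        json.dumps(summary, indent=1, default=str) + "\n")
    return summary
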