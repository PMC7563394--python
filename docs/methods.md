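# Methods

## Problem and scope

`seedshift` re-implements, as a tested pipeline, a desk procedure for
prioritizing 3′UTR single-nucleotide variants (SNVs) that change microRNA
targeting of literature-curated miRNA–mRNA pairs. The stages are: name
normalization of curated pairs, allele-aware canonical seed matching and
classification of each SNV into loss / gain / substitution of targeting, an
isoform-wide 3′UTR-exclusivity filter, tissue-expression normalization with
brain-enrichment ranking, and variant-centered conservation windows with a
Fisher exact motif presence test. Everything runs from local files; no
database or web queries are performed.

## Seed-match model

The predictive core is a canonical TargetScan-style seed matcher. With the
seed defined as miRNA nucleotides 2–8 (5′→3′), the four site types on the
mRNA-sense 3′UTR (written as DNA) are:

* `6mer` — reverse complement of positions 2–7;
* `7mer-m8` — reverse complement of positions 2–8;
* `7mer-A1` — the 6mer followed by an `A`;
* `8mer` — the 7mer-m8 followed by an `A`.

Pairing is Watson–Crick only: no G:U wobble, no 3′-supplementary pairing,
no context scoring. At one locus only the strongest applicable type is
reported (a weaker match whose span is contained in a stronger match's span
is suppressed); distinct loci may overlap. This matcher is an explicit,
reproducible stand-in for precomputed miRNA-target-site SNV databases,
which aggregate heterogeneous prediction tools; it makes no claim of
per-variant concordance with any such database.

## Variant classification

A variant's effect is assessed per curated (variant, pair): only sites whose
span contains the variant's UTR offset (including the A1 position, whose
`A` is sequence-dependent here) are considered, on the reference and the
substituted sequence. With the paired miRNA *P* and the full miRNA library:

* **loss** — *P* has ≥1 overlapping site on the reference, none on the
  alternate, and no other library miRNA gains an overlapping alternate-only
  site;
* **substitution** — *P* loses its overlapping site and ≥1 *different*
  library miRNA gains one;
* **gain** — *P* has no overlapping reference site and ≥1 library miRNA
  (any, including *P*) has an alternate-only overlapping site;
* **none** — otherwise.

Gains are assessed against the whole library because a new site for any
known miRNA constitutes new targeting. Alleles are plus-strand genomic; on
minus-strand transcripts the substituted mRNA-sense base is the complement.
U and T compare equal (UTRs stored as DNA, miRNAs as RNA).

Because one gene can appear in several curated pairs, study-style
variant-level counts reduce per-pair calls by severity
(substitution > loss > gain > none); `tally_classifications` keeps the
per-pair view and `tally_variants` the variant-level view. A variant counts
as "matched with alternative miRNAs" when any of its calls has a non-empty
gained set.

## Isoform exclusivity filter

A variant passes only if every transcript isoform covering its position
(position inside the transcript's footprint) annotates it as 3′UTR.
Non-covering isoforms are ignored — they carry no region information at
that base. A position inside a footprint but in no annotated interval
counts as `unannotated` and fails the filter, as does a variant covered by
no transcript (no gene assignment is possible) or by transcripts of two
genes (ambiguous; dropped with a logged reason). The filter is
annotation-release-agnostic: it evaluates whatever transcript models it is
given.

## Expression normalization and brain enrichment

Raw TPM-like values are transformed as `10 · log10(x + pseudocount)` with
pseudocount 1, so 0 → 0 and the scale is decibel-like (9 → 10, 99 → 20);
the transform is strictly monotone and preserves within-gene ordering.
Brain enrichment per gene is `(mean_brain + ε) / (mean_nonbrain + ε)` on
the raw scale with ε = pseudocount, ranked descending with ties broken by
gene label. The 13 default brain labels follow the GTEx tissue panel
(53 tissues, 13 brain). The ratio statistic is an explicit artifact
addition — the underlying comparison it reproduces was qualitative — and is
labeled as such in outputs.

## Conservation windows and motif presence test

For width *w* (default 100), the window around a variant at UTR offset *o*
spans `(w−1)//2` bases before through `w − 1 − (w−1)//2` bases after, so an
even-width window has the variant at offset *w*/2 and unclipped length
exactly *w*; windows are clipped at UTR boundaries with the offset
adjusted. Windows are written as FASTA for external motif tools.

Motif presence over a transcript set: a transcript is *present* if the
motif or its reverse complement occurs at least once; occurrences are
counted at every start offset in both orientations (overlaps allowed,
palindromes once per offset). Presence — not occurrence count — enters a
two-sided Fisher exact test, with two backgrounds:

* **control** (default): a control transcript set, compared by its own
  observed presence counts;
* **iid**: the expected number of present transcripts under an i.i.d.
  nucleotide model using the tested set's pooled base composition and the
  motif + reverse-complement per-offset hit probability, rounded to the
  nearest integer for the 2×2 table.

The two-sided p sums all tables (fixed margins) with probability ≤ the
observed table's. The tail is accumulated in exact integer arithmetic via
the hypergeometric weight recurrence, so ties are decided exactly; the test
suite cross-checks against an independent exact-rational enumeration (to
1e−12) and against `scipy.stats.fisher_exact`.

**Calibration note.** Under a matched foreground/background null the exact
test is discrete and therefore conservative; the p-value staircase step
near the table's mode scales with the hypergeometric mode probability,
i.e. like 1/√n. Calibration checks therefore use large transcript sets
(2000 per arm, 120 nt, a 4-nt motif giving presence probability ≈ 0.5);
with those sizes the p-value distribution over 500 matched replicates is
approximately uniform (KS ≈ 0.03–0.06). Small sets leave the exact test
visibly conservative — that is a property of exact tests, not a defect.

## Synthetic data generator

The generator emulates every input with planted ground truth, at a default
scale shaped like the motivating study: ~100 curated pairs over 20 genes
(2–4 isoforms each), 0.3–3 kb UTRs, 30 library miRNAs, and a 53-tissue
expression matrix with 13 brain tissues. Background sequence is i.i.d. with
configurable GC (default 0.45).

Planted events: an 8mer site of the gene's paired miRNA destroyed by the
variant (loss); a one-base-broken site of some library miRNA restored by
the variant (gain); a paired-miRNA site whose variant simultaneously
creates a site for a purpose-crafted partner miRNA added to the library
(substitution); and site-free positions (none). Secondary isoforms extend
the CDS into the first part of the primary 3′UTR, so variants planted in
that overlap zone are 3′UTR in one isoform and CDS in another and must be
dropped by the exclusivity filter; the remaining events sit where every
isoform is 3′UTR. Brain-enriched genes get a brain/non-brain mean ratio ρ
(default 10) under multiplicative lognormal noise (default σ = 0.25).

Every planted event is re-checked at generation time with a brute-force
Watson–Crick pairing scan of the complete emitted library — independent of
the production matcher's site-string construction — and re-planted at a
fresh location until its classification matches its label; the generator
refuses to emit otherwise. Identical seeds give byte-identical bundles.

What the generator does **not** emulate: real genomic base composition and
repeat structure, non-canonical or context-dependent miRNA sites, shared
sequence between isoform UTRs of different genes, linkage between variants,
realistic cross-species phylogeny (conservation windows carry configurable
per-site mutation instead), and GTEx's sample-level variance structure.
Passing recovery tests therefore demonstrates correctness of the machinery
on its stated model, not predictive accuracy on real 3′UTRs.

## Numerical and design choices

* Internal coordinates are 1-based inclusive, plus strand; BED-like input
  (0-based half-open) and GTF (1-based inclusive) convert at file
  boundaries only. Chromosome labels compare with an optional `chr` prefix
  stripped.
* The transcript-model TSV dialect carries 7 columns (chrom, start, end,
  transcript_id, gene_symbol, strand, region_kind) because BED6 cannot hold
  region kind, gene and transcript without packing the name field.
* Multi-allelic VCF rows split into one record per ALT; indel/MNV alleles
  are skipped with a warning (SNV-only contract).
* Alias resolution is single-hop; tables implying chains are rejected at
  load. Gene and miRNA name matching is case-insensitive; a missing species
  prefix defaults to `hsa-` (human study). A precursor miRNA name expands
  to all of its mature arms; the arm policy (`both`/`5p`/`3p`) is
  configurable because curated lists rarely state which arm was meant, and
  defaults to both (union of sites).
* Ranking ties (brain enrichment) and site-type ties (two miRNAs gaining at
  one locus) break deterministically: by gene label, and by reporting all
  gainers, respectively.
* Pipeline stages write their tables and counts independently;
  `kept + dropped = input` is asserted at every filtering stage. Reruns
  with the same configuration are byte-identical.

## Problem sizes used in checks

Oracle-equivalence checks run the matcher against a brute-force pairing
scan on 1000 random UTRs of ≤ 200 nt, the region filter against full
triple enumeration on instances of ≤ 50 transcripts, and the Fisher p
against exact-rational enumeration on hundreds of random tables. Recovery
checks use the default bundle (27 planted variants, 20 genes). Null
calibration uses 500 replicates of 2000 + 2000 transcripts of 120 nt.
These sizes were chosen so each check resolves the property it tests while
the whole suite stays quick on one CPU.

## Known limitations

* The seed matcher is canonical-sites-only; real miRNA targeting includes
  non-canonical, wobble and 3′-supplementary interactions and strong
  context dependence.
* The motif presence test's i.i.d. background ignores positional
  autocorrelation within transcripts; the control-set mode is preferred
  when a comparable transcript set exists.
* The exclusivity filter is only as good as the transcript models given;
  it implements no splice-aware consequence taxonomy beyond
  5′UTR/CDS/3′UTR.
* Curated-pair counts from the motivating literature screen are not
  reproducible without that screen's supplementary pair list; the package
  validates its machinery on the bundled 22-variant set and on synthetic
  ground truth instead.
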