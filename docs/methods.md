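# Methods

This note documents the models and conventions behind each analysis stage,
the tunable parameters and their defaults, what the synthetic cohorts do and
do not emulate, and the design choices made where the methodology was
genuinely open.

## Germline/somatic splitting without a matched normal

Tumor-only cohorts cannot subtract germline variation directly. The split
uses two resources:

* a **panel of normals**: carrier counts of each variant key
  (chrom, pos, ref, alt) across `n_normals` normal samples (default 809). A
  variant carried by **strictly more than** `pon_threshold` (default 5)
  normals is a panel hit.
* **population allele frequencies** from three databases (ExAC, 1000
  Genomes, ESP). A variant with AF > `common_af` (default 0.005) is a
  population hit. Missing AFs are treated as 0.

A variant is germline iff (panel hit OR population hit) AND not in COSMIC;
COSMIC membership scavenges the variant back to the somatic MAF on the
grounds that recurrent hotspot somatic mutations contaminate both panels and
population databases. Everything else — including rare germline variation —
remains in the somatic MAF, which therefore overestimates the true somatic
burden; this is an irreducible property of tumor-only calling, not a defect
of the implementation.

Two ambiguities are exposed as switches rather than silently resolved:

* `af_mode`: the population rule can require an excess AF in **any** one
  database (default, matching the common-SNP definition used for QC) or in
  **all** three (the literal complement of the "rare in any one database"
  retention wording — the two published phrasings are not complements of
  each other).
* `cosmic_scavenge`: whether COSMIC overrides the panel rule as well as the
  population rule (default `all`) or the population rule only (`pop_only`).

## Tumor mutation burden

`TMB = qualifying_count / capture_mb`, with `capture_mb = 45.1` (VCRome v2.1
exome) and qualifying variants defined as mononucleotide substitutions that
change the protein: `Variant_Type == "SNP"` and classification in
{Missense_Mutation, Nonsense_Mutation}. DNPs, indels, silent and splice-site
variants are excluded — the definition names amino-acid-changing
*substitutions* only. Models present in the cohort metadata but absent from
the somatic MAF are reported with TMB 0 rather than dropped.

Phase-of-therapy comparisons use the two-sided Wilcoxon rank-sum test
(`scipy.stats.mannwhitneyu`, exact when sample sizes and ties permit), with
raw p values — no multiple-testing correction across histologies, matching
how such per-histology comparisons are conventionally reported. Groups with
fewer than two models in either arm are flagged in the output, never
silently dropped.

## Breakpoints and high breakpoint density

A breakpoint is a transition between adjacent segments (same model, same
autosome, consecutive by start) whose copy change reaches `change_fraction`
(default 0.10). The change is measured on the **linear** scale,
`|2^(lrr2 − lrr1)| − 1| ≥ 0.10`, because "percent copy-number change" is a
linear-scale notion; an `lrr` (log2) difference mode is available via
`scale="log2"`. A useful consequence of the linear-ratio definition is
invariance to a global LRR offset (e.g. a ploidy/centering shift), which is
asserted by a test.

A chromosome with ≥ `hbd_threshold` (default 10, inclusive) breakpoints has
high breakpoint density, a pragmatic surrogate for chromothripsis; models
are additionally bucketed into HBD on four-or-fewer vs five-or-more
chromosomes to separate localized shattering from globally unstable genomes.
Sex chromosomes are excluded from counting entirely: without matched
normals, X/Y copy number cannot be calibrated.

## Focal events and expression rescue

Gene-level LRR is, by default, the **extreme** overlapping segment (max for
amplification, min for deletion), matching the intent of focal-event calling
where a short embedded segment carries the event; an overlap-length-weighted
mean is available via `gene_lrr_mode="weighted"`. Thresholds are inclusive:
amplification at LRR ≥ 0.538578182, homozygous deletion at LRR ≤ −1.739
(cutoffs calibrated against hallmark MYCN/SMARCB1/CDKN2A events; the
deletion cutoff is applied to the *low* tail — a homozygous deletion is
necessarily a strongly negative log ratio, so the printed "≥" on the
negative number is read as a magnitude bound).

Deletion candidates are retained only when transcription corroborates the
loss: FPKM < `rescue_fpkm` (default 5, strict) in that model, or no RNA-seq
available for the model. Candidates dropped as expressed, genes with no
overlapping segment ("uncovered") and sex-chromosome genes are all recorded
in an audit table so that every candidate is accounted for.

Exon-level FPKM (`fragment_count / ((library_size/10^6) · (exon_length/10^3))`)
supports deletion assessment at loci too sparsely probed by SNP arrays
(e.g. ATRX). No published exon-FPKM deletion threshold exists; the optional
flag (median exon FPKM < 1) is a convention of this package and is labelled
as such.

## Fusion consensus

Caller predictions are merged on the ordered (model, 5′ gene, 3′ gene)
triple — orientation matters, A→B ≠ B→A — with caller support aggregated,
frame resolved optimistically (in-frame if any caller says so) and
read-through annotation OR-ed. The filter cascade, in order:

1. **Support**: keep in-frame fusions that are recurrent (same ordered pair
   in ≥ `min_recurrent_models` = 2 distinct models of one histology) or
   supported by ≥ `min_callers` = 2 callers; union with **promiscuity**
   (a 5′ or 3′ gene with ≥ 2 distinct partners within one histology,
   computed over the full merged set, any frame).
2. **Expression**: drop pairs where *both* genes have max-over-models
   TPM < `min_tpm` = 1 (genes absent from the quantification count as
   unexpressed). Interpreted literally as "both genes below 1 TPM across
   all models" — one expressed partner anywhere keeps the pair.
3. **Cross-histology**: drop ordered pairs observed in more than one
   histology anywhere in the merged set; pediatric driver fusions are
   histology-specific, so recurrence *across* histologies indicates an
   artifact.
4. **Read-through**: drop fusions annotated read-through by any caller. An
   optional genomic-adjacency surrogate (same chromosome, gap < 100 kb) is
   provided for callers lacking the annotation.
5. **GTEx**: drop pairs observed as chimeric transcripts in normal tissue.

Each removal is recorded once, with the name of the first rule that removed
it, so `final ∪ audit` partitions the merged input — an invariant asserted in
tests. **Driver scavenge** runs last: any merged fusion whose pair is on the
driver list is restored regardless of removal reason, with provenance
`driver_scavenge` (or `filters+driver` if it also survived the cascade).
The shipped driver/GTEx/oncogene/kinase/TF lists are small editable starter
TSVs seeded with canonical entries (EWSR1–FLI1, BCR–ABL1, PAX3–FOXO1, KMT2A
partners, published normal-tissue chimeras, …), not exhaustive curated
resources; production use should substitute full lists via
`ReferenceLists.from_dir`.

The expression filter is applied after the support/promiscuity union (the
published ordering of the steps); whether recurrence should instead be
evaluated on expression-filtered calls is ambiguous in the source
description, and the chosen order is the literal one.

## Sample QC

* **Contamination (VAF skewness).** Heterozygous common-SNP VAFs cluster at
  0.5; contaminant DNA dilutes the alternate allele, shifting and skewing
  the band left. The adjusted Fisher–Pearson sample skewness of VAFs inside
  the heterozygous band (default (0.05, 0.95)) is flagged below
  `flag_threshold` = −0.5. The original procedure was visual inspection; the
  numeric threshold is this package's convention, validated by a measured
  false-positive rate ≤ 5% on clean synthetic models. Fewer than `min_sites`
  = 100 band sites yields an *indeterminate* verdict, not an exception.
* **Identity (WES–RNA).** Pearson correlation of VAFs at shared sites with
  depth ≥ 10 in both assays; matched iff r ≥ 0.61, both boundaries
  inclusive — the published decision rule. Full NGSCheckmate internals are
  deliberately not re-implemented.
* **Paired models.** Pearson r of VAFs over shared mutation keys plus the
  Jaccard fraction of shared keys; zero overlap reports Jaccard 0 and an
  undefined (NaN) correlation.
* **Human DNA content.** Technical replicates are averaged per species
  first; relative copies are `(1+E)^−(CT_unknown − CT_reference)` with
  amplification efficiency `E` = 1.0 (100%, i.e. the classic `2^−ΔCT`;
  the real assay's 90–110% efficiency window is absorbed by the exposed
  `efficiency` parameter). Two quantities are reported deliberately: the
  printed `%human = 100 · rel_human / rel_mouse` — a *ratio* that exceeds
  100 whenever human template outnumbers mouse — and the normalized
  `fraction_human = rel_human / (rel_human + rel_mouse)`, which is the
  quantity actually bounded in [0, 1]. A zero mouse signal produces an
  infinite printed percent (with a warning) and fraction 1.

## Synthetic cohorts: what they emulate, and what they don't

The generator reproduces the *statistical structure* each stage consumes:

* Per-model qualifying-mutation counts are Poisson with phase-specific
  means, `rate × 45.1 Mb`; default rates 2.57 (diagnosis) and 3.08
  (relapse) mutations/Mb — the cohort-level medians the analysis is designed
  around. Clonal VAFs are Beta-distributed around 0.5 (concentration 60)
  and observed through binomial sampling at Poisson(120) depth.
* Common germline SNPs come from a shared site pool with panel carrier
  counts > 5 and ExAC AF > 0.005; rare germline sites have ≤ 5 carriers and
  all AFs < 0.005; scavenge-back cases look germline but carry the COSMIC
  flag. Rare-germline and scavenged variants are planted with
  non-qualifying classifications so the planted qualifying-SNV count per
  model is exactly the TMB numerator — a bookkeeping choice that keeps the
  planted burden identifiable.
* Segment profiles place exactly the requested number of ≥ 10% transitions
  per planted chromosome (log2 steps ≥ 0.25, well clear of the threshold);
  unplanted chromosomes are single segments with ±0.02 LRR noise, so planted
  counts are exact, not merely expected. Focal plans insert a segment at the
  target LRR over the gene, with the model's FPKM forced low (< 1) or high
  (20–80) according to the planted expression state.
* The fusion plan plants every class the cascade must handle: recurrent
  in-frame pairs, two-caller singletons, a driver planted so the filters
  remove it (frame unknown, single caller) and only scavenging restores it,
  promiscuous partners, single-caller noise, read-throughs, GTEx pairs,
  cross-histology pairs, and pairs with both genes silenced (< 1 TPM
  everywhere).
* A per-model contaminant fraction c serves double duty: heterozygous VAFs
  are observed at `0.5·(1−c)` (binomial), and the qPCR CT table receives
  mouse template in proportion c — one number drives both QC signals.
* All randomness flows from the single config seed through one
  `numpy` Generator; identical (config, seed) produces byte-identical
  fixture files, asserted by hashing.

Not emulated: read-level data (no FASTQ/BAM), realistic mutational
signatures or positional clustering, linkage between variants, caller-
specific error profiles beyond the planted classes, segmentation noise
autocorrelation, or subclonal structure. Passing tests therefore demonstrate
that the *rules* are implemented correctly and recover planted structure
under the assumed noise model — not that the thresholds themselves are
optimal for any particular real cohort.

## Numerical and degenerate-input conventions

* All rule thresholds are applied with the exact comparison documented
  (strict `> 5` for the panel, strict `> 0.005` for AF, inclusive `≥ 10`
  for HBD, inclusive LRR cutoffs, strict `< 5` FPKM rescue, inclusive
  `≥ 0.61`/`≥ 10` identity boundary); boundary behavior is bit-exact and
  tested at `nextafter` resolution.
* Empty inputs return empty, correctly-typed outputs (an empty cohort runs
  through the whole pipeline with zero counts and no errors).
* Validation failures name the offending rows/fields; QC guards
  (insufficient sites) return indeterminate verdicts rather than raising.
* Problem sizes in the test and acceptance workloads (12–50 model cohorts,
  100–500 simulation replicates) were chosen as the smallest sizes at which
  the stochastic checks are statistically stable.

## Known limitations

* The panel of normals is keyed on exact variant identity; positional
  fuzziness (indel normalization) is out of scope.
* Manual curation steps of the original workflow (visual inspection of
  focal events, curated edits) are inherently non-algorithmic and are
  represented only by the audit tables that make such review possible.
* The identity check is a direct VAF correlation, not a full genotype
  likelihood model; it inherits the published operating point.
* Starter reference lists are intentionally minimal (see above).
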