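# Methods

## Problem and model

A targeted gene panel observes only a small, driver-enriched slice of the
coding genome. Panel TMB is therefore a rescaled, noisy and *biased*
estimate of exome TMB: biased upward because driver genes carry more
mutations per base than the coding average, and noisy because a footprint of
*F* Mb quantises TMB in steps of 1/*F* mutations per Mb. This package
models the whole measurement chain — footprint definition, variant
counting, dichotomisation, threshold calibration — and provides a synthetic
cohort generator with known ground truth so every stage can be verified.

## Footprints

The interrogated region of a panel is approximated by the **longest open
reading frame** of each panel gene: for every gene the transcript with the
maximal summed CDS length is selected (ties broken by lexicographically
smallest transcript id, for determinism), and all selected CDS intervals are
merged. "Longest ORF" is interpreted as coding length, not genomic span.
Internally all coordinates are 0-based half-open; GTF input (1-based
inclusive) is converted on read. Overlapping *and touching* intervals merge,
so footprint sizes count each base once. Gene matching is by symbol,
case-sensitive, with an optional synonym map; panel genes without an
annotation match or without any CDS (e.g. promoter-only panel content) are
excluded with a warning and reported in the footprint summary. Real
commercial designs also include non-coding content and are generally
*smaller* than the longest-ORF approximation; reconstructing proprietary
probe designs is out of scope.

A variant belongs to a footprint if **any base of its reference span**
(anchor-base convention for indels) overlaps it — the any-overlap rule
matches how a capture design would observe the event. Inputs are assumed
left-aligned/normalized; no re-normalization is performed.

## TMB, ML and concordance

- Panel TMB = in-footprint events / footprint Mb. All classes (SNV, MNV,
  indel) count once per ALT allele; synonymous and non-synonymous events
  both count by default, with a `nonsynonymous_only` switch.
- Exome TMB = in-CDS-union events / 30 Mb. The 30 Mb denominator is a
  reporting convention held fixed regardless of the annotation's true CDS
  size; an override (`"cds"` = true CDS-union Mb) exists for sensitivity
  analysis and is used throughout the miniature-genome tests, where panel
  and exome TMB must share a scale.
- ML = genome-wide count of events flagged non-synonymous (consumed from a
  configurable INFO key, default `NS`; coding consequence is not predicted
  de novo). ML is not restricted to any footprint.
- TMB-high means TMB ≥ cut-off, applied identically to both axes; the exome
  call is the reference. Misclassification = FP% + FN% (exact identity,
  before any display rounding; percentages are rounded to one decimal only
  for display).

## Calibration

The calibrated cut-point maximises **accuracy** (fraction of samples
classified into the right category), matching the stated goal of putting
the most patients in the correct TMB class; Youden's J would instead
balance sensitivity and specificity regardless of class sizes. Candidate
thresholds are midpoints between adjacent distinct panel-TMB values plus
sentinels below the minimum (all-positive) and above the maximum
(all-negative); accuracy ties resolve to the lowest threshold. Reporting
midpoints decouples the calibrated value from the score granularity of one
cohort. AUC is computed by trapezoidal integration over the ROC sweep
(scikit-learn), which with rank-averaged ties equals the Mann–Whitney
probability-of-correct-ranking statistic; the test suite checks this
equality to 1e-12 against an independent pair-counting oracle. Strata with
a single exome class raise a "ROC undefined" error and are skipped with a
warning in the batch driver.

## Regression

ML on exome TMB is fitted per tumour type by plain OLS (scipy), n ≥ 3
required, degenerate predictor rejected, constant response returned as a
flat line with R² = 0. The fit reports slope, intercept, R², n and the
textbook homoscedastic slope standard error. Note that on simulated data
the ML noise is binomial with variance proportional to the mutation count,
so the homoscedastic SE understates the true sampling spread of the slope;
the acceptance test therefore checks slope recovery against the exact
standard error implied by the generator's noise model,
sqrt(Σ wᵢ² Nᵢ ν(1−ν)) with OLS leverage weights wᵢ.

## Synthetic cohort generator

The generator defines the study conditions for all cohort-scale tests.

**Genome.** 2000 non-overlapping genes on 4 chromosomes; per-gene coding
length log-normal with mean 2 kb (σ = 0.45, clipped to 0.3–9 kb), split
into 1–6 exons; CDS union ≈ 4 Mb. Each gene's primary transcript carries
all exons; 0–2 secondary transcripts carry contiguous exon subsets, so the
gene's CDS union always equals its longest ORF and the all-gene footprint
equals the exome region set by construction. 30% of genes are designated
drivers.

**Panels.** Seven nested panels named after the field's well-known assays,
with footprint targets 0.375–0.7125 of the CDS union (≈1.5–2.85 Mb). The
1.9× largest:smallest ratio mirrors the relative spread of real panel
footprints (0.78 vs 1.48 Mb). Every panel contains all driver genes plus
length-targeted filler, so smaller panels are more driver-concentrated —
the mechanism behind panel-size-dependent over-calling. The panel:exome
footprint ratio is deliberately *compressed* relative to reality (≈40–70%
of the exome instead of a few percent): panel TMB resolution is 1/*F* per
Mb, and resolving cut-points near 10/Mb to fractions of a mutation/Mb at
desk-scale cohort sizes requires footprints above ~1 Mb. Consequently
absolute misclassification rates are milder than a realistically tiny panel
would show; the *ordering* (smaller panel → worse concordance, higher
calibrated cut-point) is preserved.

**Mutation model.** Per sample, a target TMB (mutations per CDS-Mb) is
drawn from the tumour type's log-normal; with probability *h* it is
multiplied by the hypermutator factor. Defaults (median/σ/h/multiplier):
colorectal 4/0.9/0.15/8 (MSI-like tail), skin 12/1.0/0.05/4, lung
9/0.9/0.03/4, breast 3/0.8/0.03/5 — chosen as realistic metastatic-cohort
values with colorectal hypermutators reaching the 30–40/Mb range. The
Poisson event count (mean TMB × CDS Mb) is placed multinomially over genes
with weights (ORF length) × (enrichment for drivers, default 2.0);
enrichment redistributes mutations without changing the genome-wide count,
so it inflates panel TMB while leaving exome TMB untouched. Variant class
mix SNV/MNV/INDEL = 0.88/0.04/0.08; non-synonymous probability per class
0.75/0.90/0.90 (effective non-synonymous fraction ν ≈ 0.768, making the
analytic ML~TMB slope ν × CDS-Mb under the CDS denominator override).
Positions are uniform over the gene's primary CDS; alleles are random bases
(no reference sequence or trinucleotide signature model — see limitations).
Indels are 1–10 bp with a VCF anchor base.

**Reproducibility.** Every sample has its own RNG stream keyed on
(seed, crc32(sample id)); annotation, panel assembly and type assignment use
separate fixed substreams. The same configuration yields byte-identical
GTF and VCF output. Truth bookkeeping (exome count, per-panel counts by
gene membership, non-synonymous count) is recorded during generation,
independent of the interval code that later recounts it; gene placement
guarantees intergenic gaps (≥200 bp) exceed the maximal deletion span, so
gene membership and footprint overlap agree exactly.

**What passing tests do and do not show.** The generator reproduces the
cohort *structure* that drives panel/exome discordance — heavy-tailed
per-type TMB, driver enrichment, class mix, footprint-size spread — so
green tests demonstrate the pipeline's arithmetic, the over-calling
mechanism and the calibration machinery. They do not demonstrate behaviour
under real mutational signatures, regional mutation-rate variation, FFPE
artefacts, germline contamination, subclonality/purity effects or true
vendor panel content, none of which the generator models.

## Problem sizes and numerical choices

Cohort-scale tests use 120–500 samples on the default 4 Mb genome (a few
seconds each); unit oracles use per-base brute-force comparisons on
hundreds of random fixtures. Determinism is asserted at the byte level for
generator output and the pipeline's JSON summary. Degenerate inputs are
hard errors with named causes: empty allele/identical ref-alt, zero-match
panels, empty cohorts, single-class ROC strata, missing ML annotation,
missing metadata columns, sub-minimum regression n.

## Known limitations

- Longest-ORF footprints overestimate coding panel content and ignore
  non-coding baits; calibrated cut-points on real assays will differ.
- Panel:exome footprint ratio compressed at desk scale (above).
- No variant normalization; discordantly represented indels in real VCFs
  should be pre-normalized.
- The 30 Mb exome convention, not the annotation's true CDS size, scales
  exome TMB on real data; comparisons against other exome-TMB reports must
  use the same convention.
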