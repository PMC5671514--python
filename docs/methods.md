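# Methods

This note documents the models, rules and numerical choices behind
`primirna`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinates and interval algebra

All interfaces use GFF3/GTF convention: 1-based, both ends inclusive.
`overlap_bp` counts shared bases; `gap_bp` counts bases strictly
between two intervals (0 when overlapping or book-ended, undefined
across chromosomes). Any internal half-open representation (the
interval index) is invisible at the API. Strand is recorded but ignored
by default in all overlap/gap logic — positional grouping of pri-miRNAs
is defined on genomic extent, not orientation — and a `stranded` flag
switches on strand-aware mode where wanted. "Overlap with a gene"
always means the gene's full genomic span, not exon-level overlap:
gene records are the unit of the reference annotations this pipeline
consumes. Unknown GFF3 feature types are counted and skipped, never
guessed into a biotype.

## Positional classification and model assignment

Classification runs twice. The **hairpin pass** labels each hairpin
(pre-miRNA): G3A if it overlaps a protein-coding gene, else G4 if it
overlaps a non-coding gene, else G2 if the nearest protein-coding gene
is 1–400 bp away, else G1. The **model pass** applies the same ladder
to the final model interval, with G3B inserted after G3A for models
that overlap a coding gene their member hairpins do not touch. The
precedence order G3A > G3B > G4 > G2 > G1 is fixed; the group
definitions do not state an order for features satisfying several of
them, so the most specific (coding overlap) wins and proximity loses to
any overlap. The 1–400 bp window is inclusive at both ends and is
measured on each pass's own interval (hairpin pass: the hairpin; model
pass: the model).

Model assignment per hairpin: a G3A hairpin adopts the host
protein-coding gene's coordinates (largest overlap wins when several
genes overlap; exact ties are deterministic — leftmost start, then id —
and flagged). Otherwise the matched transcript prediction provides the
interval, and with no prediction the hairpin's own annotation is kept.
Hairpin–prediction matching requires ≥ 1 bp overlap; among several
candidates the largest hairpin overlap wins with the same deterministic
tie-break. Prediction-derived models must contain their member
hairpins, so a partially overlapping prediction is extended to the span
of prediction ∪ hairpin and flagged.

Two-hairpin models arise only through a shared interval source (one
prediction spanning two hairpins, or one host gene containing two);
proximity alone never merges. A prediction claimed by more than two
hairpins keeps the two largest overlaps and is flagged; a host gene
containing more than two hairpins is chunked into flagged ≤ 2-member
models. Final models that overlap each other are flagged, not edited:
resolving such conflicts (a handful of cases in real data) is left to
manual curation, and the conflict report replaces it.

The report validates two identities: per group,
`final models = prediction-derived + reference-derived`; at totals
level, `hairpins = final models + two-hairpin models`. The second holds
only in total because hairpin-level and model-level groups differ for
any hairpin whose model changes group (every G3B model, for instance,
has its hairpin counted under G1 or G2).

## Read counting

A record is admitted if mapped, primary (not secondary/supplementary)
and MAPQ ≥ 10 (configurable). Multi-mapping reads are therefore counted
exactly once, via their primary record. Admitted reads are assigned to
the feature with the largest number of overlapping bases; equal-overlap
ties are left unassigned and tallied as ambiguous rather than
arbitrarily resolved. Overlap is measured on reference-consuming CIGAR
operations with N (intron skip) treated as a gap and D (deletion) as
aligned span. For paired data the default counts fragments: both
mates' overlaps are pooled per read name before the largest-overlap
rule; a flag switches to per-record counting (appropriate for
single-end libraries). Library sizes are the column sums of assigned
counts. The accounting identity
`records = filtered + admitted; admitted fragments = assigned +
ambiguous + no-overlap` is exposed in the statistics and tested.

## Differential expression

Counts are modelled NB with variance μ + φμ²; φ = BCV². One exact-test
engine serves both replicated and unreplicated designs; replicating any
particular published implementation bit-for-bit is a non-goal — the
acceptance surface is distributional correctness on simulation
(type-I error, power), plus a cross-check against the reference R
implementation on a small fixture where the two approaches coincide.

* **TMM normalisation** (on by default, as in the standard workflow;
  whether the original analysis applied it is not stated, so it is a
  flag): M-values trimmed 30 % per side, A-values 5 %,
  precision-weighted mean of surviving log-ratios; factors rescaled to
  multiply to 1. Reference sample: upper-quartile CPM closest to the
  mean upper quartile.
* **Library equalisation**: counts are mapped to the geometric-mean
  effective library size by a quantile-matching transform under the
  working NB (average of the normal and gamma continuous
  approximations, half-count continuity shift, floored at 0). Equal
  libraries pass through unchanged.
* **Dispersion**: `fixed_bcv` sets φ = BCV² for every feature (0.4 →
  0.16, the recommended value for designs without replicates); `common`
  maximises the summed conditional NB log-likelihood of the equalised
  counts over φ ∈ [1e-6, 10] (1-D bounded search on log φ, two
  pseudo-count refinement passes); `tagwise` maximises each feature's
  conditional likelihood plus `prior_weight` (default 10
  pseudo-observations) times the across-feature average likelihood
  curve, on a log grid that always contains the common value — so
  weight → ∞ collapses to common and weight 0 gives per-feature MLEs.
  Estimation requires ≥ 2 samples per group; a single replicate carries
  no dispersion information and raises with a pointer to fixed-BCV
  mode.
* **Exact test**: condition one group's (rounded) pseudo-count sum on
  the total; under the null the sum follows the NB conditional law with
  sizes n_g/φ. The two-sided p-value sums all outcomes no more probable
  than the observed one (with a 1e-10 relative tolerance for
  floating-point ties); φ < 1e-8 uses the binomial limit. Totals above
  50,000 are evaluated on a ± 60-SD window around the conditional mean
  (the truncated mass is far below double precision). log2FC is
  test-over-reference on normalized group means with a 0.125-count
  prior to avoid infinities (any small constant would do); `aveExpr` is
  the average log2 CPM with the same prior. Features with zero total
  report p = 1, log2FC = 0. No independent filtering precedes testing.
* **FDR**: Benjamini–Hochberg step-up (via statsmodels), with input
  range validation.

## Group evaluation

Detection = summed counts across one experiment's libraries ≥ 4
(configurable); "accumulated reads" sums over all of that experiment's
libraries, both genotypes. The group-shift test is a one-sided Wilcoxon
rank-sum of a group's log2FC against a background set — by default all
protein-coding features in the DE table, since the original comparison
set is not stated and this is the natural null population; the p-value
is exact by enumeration when the pooled size is ≤ 20 with no ties,
otherwise a tie- and continuity-corrected normal approximation (this
matches the conventional `wilcox.test` switch, so published per-group
p-values computed on unavailable data are not expected to reproduce
bit-for-bit). Contingency tables classify each common feature by the
sign of log2FC in each experiment; exact zeros are excluded and
counted, and cell totals must conserve the common set. The FDR filter,
when requested, applies to experiment A only — the design mirrors
comparing a replicated experiment (FDR-filterable) against an
unreplicated one (sign only).

## Synthetic data

The generator emulates the statistical structure the pipeline is built
for, not sequence. A single chromosome is laid out as shuffled,
independent cassettes (one per model, plus background genes) separated
by gaps drawn from 800–1,600 bp — larger than both the 400 bp proximity
window and the maximum prediction extension (300 bp), which makes every
truth label unambiguous by construction; an internal exhaustive-scan
check re-derives the labels at generation time and refuses to return
inconsistent truth. An adversarial mode instead places boundary cases
(G2 gaps of exactly 400 bp, companion genes at 401 bp) for classifier
edge tests.

Defaults are the study conditions: 325 hairpins forming 318 models
(G1 194, G2 26, G3A 54, G3B 37, G4 7; seven two-hairpin models split
2/0/3/1/1), per-group prediction fractions chosen so 77 models are
prediction-derived (28/7/0/37/5); four libraries (two wild type, two
mutant) at the experiment's quantified read depths (18.9, 19.4, 18.6,
20.9 million); BCV 0.4. True effects: the direction (up-regulation of
pri-miRNAs in the mutant) is established; the magnitude is not stated,
so the defaults place log2FC = +2 on G1/G2/G3B/G4 models — a clear but
realistic accumulation — and +0.5 on G3A models, whose host-gene
coordinates dilute the pri-miRNA signal with the protein-coding
transcript; background genes draw log2FC ~ N(0, 0.25) and baseline
expression log2 CPM ~ N(3, 2). Counts are gamma-Poisson
(variance μ + φμ²), Poisson at BCV 0. Simulated SAM files place
uniform single-end primary reads (MAPQ 50) inside their source
feature. All generators are bit-reproducible from (config, seed).

What passing the closed-loop tests shows: the classifier, builder,
counter and test behave exactly as specified on data satisfying their
assumptions. What it does not show: robustness to real-data properties
the generator omits — spliced and antisense transcription, overlapping
gene models, fragmented assemblies, mapping artefacts, non-NB
overdispersion — beyond the ambiguous-layout classifier tests and the
flagged-conflict paths exercised separately.

## Problem sizes

The shipped simulations use the study-scale annotation (≈ 1,500
features), 2,000-feature count matrices for calibration/power checks,
and enumeration oracles at the sizes where enumeration is exact
(rank-sum pooled n ≤ 12 in tests, conditional totals ≤ 50). These sizes
give stable Monte-Carlo estimates while keeping the default test run
fast.

## Known limitations

* The exact NB test approximates unequal libraries through the
  quantile-matching equalisation; severe depth imbalance (beyond the
  ~10 % of the default libraries) degrades calibration gracefully but
  is not characterised here.
* Group assignment uses full gene spans; intronic vs exonic hairpin
  placement is not distinguished.
* Overlapping-model conflicts are reported, never auto-resolved.
* The pipeline consumes assembler output; it does not assemble
  transcripts or align reads.
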