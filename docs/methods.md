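# Methods

## Model

The toolkit manufactures ground truth for mosaic variant calling from
mixtures of samples with established, mutually exclusive germline
genotypes. Three assumptions carry the whole construction:

1. **Diploidy and copy-number neutrality.** A donor sample present at
   mass fraction *f* contributes *f* of the DNA at every locus, so a
   heterozygous donor variant is expected at VAF *f*/2 and a homozygous
   one at *f*. Loci where any constituent sample shows |log2
   copy-number ratio| ≥ 0.3 are excluded from positive sets because the
   arithmetic breaks there; positions not covered by any copy-number
   segment are treated as CN-unknown and conservatively excluded from
   positives (they remain eligible as negative candidates, where only
   the reference-homozygous state matters).
2. **Exclusivity by explicit assertion.** A variant enters a donor's
   private set only if both callers PASS-call it with concordant
   zygosity in the donor *and* both callers explicitly genotype every
   other sample reference-homozygous at that position. A no-call is
   never accepted as evidence of absence: truth-set purity depends on
   positive confirmation. Zygosity disagreement between callers yields
   NO_CALL rather than a majority vote, because "called by both" is read
   as full genotype concordance. Multi-allelic records are split to
   bi-allelic sites first, and a sample carrying a *different* alt at
   the same position is treated as non-reference there, which excludes
   the site.
3. **Equal library efficiency.** Mass fractions convert to read
   fractions one-to-one (equal genome size and library efficiency across
   sources) — the same implicit assumption DNA-mass mixing makes.

All variant comparisons run on a normalized representation:
parsimony-trimmed alleles with left alignment against the reference
(standard chop-shared-suffix / extend-left loop), 1-based VCF
coordinates internally, BED half-open intervals converted at the I/O
boundary.

## Mixture products and the reference design

A product is a set of (donor, mass fraction) components; the internal
reference takes the remaining fraction. Fractions are stored as exact
rationals (`fractions.Fraction`), so designed-VAF equality, distinctness
counts and threshold comparisons never suffer float collisions; floats
appear only at I/O edges. The package ships the published 39-product
design (9 M1-class products over {V1, V2}, 12 M2 over {V1, V3, V4}, 18
M3 over {V1, V3, V5}) and the published cardinalities of the five
variant sets (2,925 / 6,732 / 2,318 / 2,323 / 6,363 records; 19,936
germline negatives). `planted_vsets()` materializes schematic variant
sets at exactly those cardinalities so the truth-set arithmetic (per-
product counts, totals, designed-VAF proportions) runs at full scale
without sequencing data. The designed-VAF summary counts one
(zygosity-class, product) combination per appearance of a donor set —
unweighted by variant counts — which is the convention under which the
published percentages (V1 100%, V4 50%, V2 ≈ 55%) arise.

Product selection itself (which 9/12/18 of the possible ratio
combinations to sequence) is user input; no covering-efficiency
optimizer is provided.

## In-silico mixing

Physical DNA mixing is emulated per read pair: source *i* with mean
depth *d_i* is thinned with keep probability *f_i · D / d_i* for target
depth *D*. The keep decision hashes the read name with a key derived
from (seed, sample id) — both mates share one fate, the selection is
independent of file order, and identical recipes reproduce identical
read sets. Mean depth is estimated as aligned bases over reference
length. Read groups record each read's source sample.

Set-B construction downsamples the internal reference to the mixture
depth, deletes every reference read whose *aligned span* (deletions
included, soft clips excluded — the pileup convention) overlaps a
positive-control interval, and splices in all mixture reads overlapping
those intervals. Extraction intervals default to the exact ref-allele
span of each positive (a single base for SNVs); padding is the caller's
choice via the interval inputs. Removal and extraction act on single
reads, mirroring interval-intersection semantics, so a mate pair can be
split at an interval edge; downsampling itself never orphans a mate.
Duplicate flags are carried through unchanged, never recomputed.

## Post-filtration

Raw allele counts come from a samtools-convention pileup: clipped bases
are invisible, a deletion spanning the position adds depth but no
allele, insertions/deletions are keyed at their anchor base, and counts
are stratified at BQ ≥ 30. All boundary comparisons are literal:
strictly-below-threshold removes, the threshold value itself survives.

- **Positives**: removed when mean depth across all products < 40×, or
  when the variant materializes (≥ 1 high-BQ alt read, configurable) in
  fewer than 20% of the products designed to carry it.
- **Set-A negatives**: removed below 20× mean depth, or when any single
  product shows more than three high-BQ alternate alleles — the final
  catalogue is shared across all mixtures, so one contaminated product
  disqualifies the position.
- **Set-B germline negatives**: heterozygous sites must be consistent
  with a beta-binomial allele-balance model (defaults α = 74, β = 76,
  the values fitted on internal-reference heterozygous SNPs; two-tailed
  p ≥ 0.01, total alt reads against pileup depth, not BQ-stratified);
  homozygous sites must keep VAF ≥ 0.9; a site missing (zero alt reads)
  in any product is removed. Whether a single failing product suffices
  is in principle ambiguous; the default is "any product fails →
  removed", and the per-product loop makes other policies easy to add.

The two-tailed p-value uses the minimum-likelihood convention for
discrete exact tests: p(k) = Σ P(j) over outcomes j with P(j) ≤ P(k),
with a 1e-9 relative tolerance on the pmf comparison to absorb float
ties. The pmf comes from `scipy.stats.betabinom` (log-space internally,
stable at n ≈ 1,100); the test suite checks it against an independent
log-gamma summation oracle to 1e-10 for all n ≤ 200. Under the model
the test rejects slightly under the nominal 1% (exactly 0.98% at
n = 1,100), so multi-product removal rates land in the 1–2% range for
two to three products. Parameter fitting is maximum likelihood on
(log α, log β) with L-BFGS-B from a moment-flavoured start; degenerate
inputs (all counts at a boundary) are rejected, and pure-binomial data
drives α+β toward the upper bound, which callers can read as a
no-overdispersion signal.

## Evaluation

Calls are matched to truth by exact normalized (chrom, pos, ref, alt).
Matches to the positive catalogue are TP; position matches to the set-A
catalogue are artifact FPs; site matches to the set-B germline catalogue
are germline FPs; anything else is FP_UNKNOWN, reported but excluded
from rates because the negative catalogues are explicit. Sensitivity is
also stratified over half-open expected-VAF bins (default edges 0, 1%,
5%, 10%, 30%, 100%, reflecting the low-VAF regime of interest).

VAF concordance groups positives by (variant type, expected VAF), takes
the median observed VAF per group — pooled across all products — and
computes Pearson's r between log10(expected) and log10(median observed),
separately for SNVs and INDELs. Groups with median zero cannot enter a
log-scale fit; they are excluded and reported rather than pseudocounted.
A single expected-VAF level leaves the correlation undefined and is
reported as such.

## Synthetic data generator

The generator emulates the study design at desk scale: a single random
contig (GC fraction configurable, default 0.5), several diploid samples
each carrying private variants plus a shared germline background
(het:hom 5:1, INDELs at a configurable fraction, sizes 1–3 bp), two
pseudo-callers derived from the truth with configurable dropout and
zygosity-error rates (default 0 — the callers also emit the explicit
0/0 assertions the selection logic requires), flat log2 = 0 copy-number
tables with optional planted aberrations, and paired-end reads written
directly as coordinate-sorted BAM with correct coordinates and CIGARs —
no aligner is involved, because the artifact tests mixing and filtering,
not alignment.

Reads: fragments are placed uniformly with insert sizes ~
Normal(300, 30) clipped at read length + 10; heterozygous variants land
on a per-fragment coin flip (unphased — adequate because planted
variants are spaced at least two read lengths apart, beyond typical
fragment overlap); per-base errors at 0.1% substitute a random other
base; base qualities are 37 with a 7% admixture of 20, so ~93% of bases
clear BQ 30. Everything is deterministic under (seed, sample id), with
per-purpose RNG streams.

What the generator does **not** model: exome-capture bias (coverage is
uniform; capture data is overdispersed, which is exactly why the
beta-binomial filter exists — an optional beta-binomial depth mode would
exercise it more realistically), sequencer-specific error profiles,
PCR duplicates, contamination, and structural variation. Passing tests
therefore demonstrate the correctness of the construction and filter
logic, not robustness to every artifact class of real WES data.

## Problem sizes and numerical choices

The test suite runs the read-backed pipeline on a 30 kb contig, 3
samples, 12 private variants each, 150× per-sample depth and 110–120×
mixtures; the truth-arithmetic checks run at the full published scale
(386,613 records) since they need no reads. Stochastic assertions use
binomial bounds: 3σ on pooled counts, 4σ per site (hundreds of sites
are checked, so a 3σ per-site bound would false-alarm). The acceptance
script simulates 1,000 sites per designed SNV VAF level at 1,100×.
Fraction sum-to-one validation uses a 1e-9 tolerance; VAF equality in
design arithmetic is exact-rational.

## Known limitations

- Single-caller INDEL rescue only flags candidates (NEEDS_REVIEW); the
  visual-review step it models is inherently manual, so promotion
  requires an explicit accept list.
- gVCF-style reference blocks are not expanded; inputs must assert
  REF_HOM explicitly per position (the synthetic generator and the
  `simulate` command produce such callsets).
- Set-B read replacement can split mate pairs at interval boundaries
  (single-read semantics); pileup-based filters are unaffected, but
  insert-size statistics near positive positions are not meaningful.
- The evaluator scores binary call sets; no ROC over caller-internal
  thresholds.
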