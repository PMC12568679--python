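# Methods

This note documents the models implemented in `enhancerscape`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that affect results.

## Peak calling

Coverage is binned (default 100 bp); a fragment increments every bin it
overlaps. The background rate λ is the median bin count, floored at 0.1 —
the median is robust to a minority of enriched bins, which is what makes the
caller's monotonicity property hold (raising one bin never removes a peak
elsewhere when there are more than two bins). Each bin gets a one-sided
Poisson upper-tail p-value P(X ≥ count | λ); Benjamini–Hochberg is applied
across bins (α default 0.05) and runs of significant bins merge into peaks.
The summit is the leftmost base of the highest-count bin; the peak score is
−log₁₀ of the best bin p-value, computed on the log scale so that very strong
peaks keep distinct scores instead of saturating at the smallest positive
double (distinct scores matter downstream, where IDR ranks them).

This is a deliberately minimal, fully specified caller: no local-λ cascade,
no fragment-size model, no control track, and peaks narrower than one bin are
not representable. It is calibrated (expected false peaks ≤ α × bins on pure
background, in practice near zero) but not intended to match any production
caller numerically.

## IDR: the copula mixture

Within a group, the two deepest replicates are paired: candidate pairs are
mutually overlapping peaks, matched greedily by smallest summit distance,
then larger overlap, then coordinate, each peak joining at most one pair.

Pair scores are rank-transformed (average ranks for ties) to uniforms
u = rank/(n+1) and mapped through the inverse CDF of the *current* marginal
mixture π₁·N(μ, σ²) + (1−π₁)·N(0, 1) — the pseudo-likelihood device for
copula mixtures. The joint model is a two-component bivariate normal: the
irreproducible (null) component is standard bivariate normal with correlation
0; the reproducible component has common mean μ, variance σ² and correlation
ρ. EM alternates responsibilities and moment updates, re-deriving the
pseudo-data each iteration; convergence is declared when no parameter moves
by more than 10⁻⁶ (500 iterations maximum).

Three numerical choices stabilize the fit, all motivated by measured failure
modes rather than aesthetics:

- **Adaptive transform, not a fixed normal-quantile transform.** Mapping
  ranks through Φ⁻¹ alone forces the pooled marginal to be standard normal,
  which squashes μ toward zero and biases π₁ upward by ~0.15 at moderate
  mixing; the adaptive map keeps the null margin standard normal while the
  reproducible component carries its own location and scale.
- **Pseudo-count penalty on π₁** (κ = 0.02 n in the mixing-weight update).
  When the two components coincide — pure-null input — the likelihood is flat
  in π₁ and EM drifts arbitrarily; the penalty resolves the ridge toward
  π₁ → 0, while biasing identifiable fits by at most ~2 %.
- **Deterministic multi-start** (four fixed initializations, best final
  pseudo-log-likelihood wins) and a σ² floor of 0.09. EM on adaptive
  pseudo-data can stall in a start-dependent local solution for
  near-comonotone scores, and σ can otherwise collapse onto a thin slab of
  the diagonal.

Local IDR is the posterior null probability; global IDR of a pair is the mean
local IDR of all pairs at least as reproducible (a running mean of the sorted
local values, hence monotone and in [0, 1]). Filtering keeps pairs with
global IDR ≤ 0.05 by default — the conventional cutoff; the retained peak is
the union interval with the higher-scoring member's summit. Recovery is
tested, not assumed: over π₁ ∈ {0.3, 0.5, 0.7, 0.9} × ρ ∈ {0.6, 0.8, 0.95}
at n = 2000, the median |π̂₁ − π₁| is ≈ 0.04.

With three or more replicates, IDR runs on the two deepest samples by
fragment count, mirroring common ENCODE-style practice.

## Consensus peaks

Three steps: pool all samples' fragments, call peaks on the pooled coverage,
and keep a pooled peak iff some IDR peak has at least fraction F (default
0.5) of *its own* length inside the pooled peak — the `-F` (fraction of the
B feature) reading of `bedtools intersect`, with an inclusive bound. Group
IDR sets are unioned before the intersection so that sites strong in any one
group survive.

## Signal normalization

Counting assigns a fragment to the peak with the larger overlap (ties to the
lower coordinate), after interval-merging any overlapping consensus peaks, so
column sums equal assigned fragments. TPM is rate = count / length(kb)
normalized to 10⁶ per column. TMM factors follow the standard recipe: the
reference column is the one whose 75th-percentile count/library-size is
closest to the mean of those percentiles; M and A values over rows nonzero in
both are double-trimmed (30 % per tail on M, 5 % on A); the factor is 2 to
the precision-weighted mean M; factors are rescaled to geometric mean 1, and
fewer than 10 usable rows falls back to factor 1 with a warning. The
implementation is cross-checked in the test suite against Bioconductor
edgeR's `calcNormFactors` (2 % relative tolerance). Final signal is TPM
divided by the TMM factor — normalization within sample first, scaling
between samples second.

## Promoter/enhancer classification and annotation

A peak is a promoter iff it overlaps a strand-aware TSS window, default 1 kb
upstream and 500 bp downstream (on minus-strand genes upstream extends
rightward); everything else is an enhancer. The window is configurable
(± 1.5 kb is a common alternative convention). Genomic features are assigned
by first match in the priority order promoter_region → 5′UTR → 3′UTR → exon →
first_intron → other_intron → downstream (≤ 3 kb past the gene end) →
distal_intergenic, with non_coding available for annotated non-coding genes;
genes without exon structure are treated as single-exon. "First" intron is
transcription-order first. TSS distance is signed (negative = upstream),
measured from the peak midpoint — the midpoint is symmetric and
deterministic — and binned into 0–1, 1–3, 3–10, 10–100 kb, 100 kb–1 Mb and
> 1 Mb.

## Dynamic enhancers and trend profiles

Per-peak group means (L, M, H) feed a coefficient of variation (sample SD /
mean, pseudocount 10⁻⁹); peaks with CV above the threshold (default 0.5) are
ranked by variance of group means and truncated to the top K (default 5000).
The log₂ fold-change series (0, log₂ M/L, log₂ H/L) (pseudocount 10⁻⁹) is
assigned to the best-Pearson-correlated template among all integer series
(0, a, b), |a|, |b| ≤ c (c default 2, 24 candidates), ties to the smaller
profile id; flat series are excluded. Direction is up for non-decreasing
templates ending above zero, down for the mirror, otherwise other.

The enrichment test replaces a large-T permutation approximation with the
exact small-series version: for each assigned peak all 6 orderings of its
group means are enumerated and re-assigned; a profile's expected count is the
summed match fraction (so expectations total the number of assigned peaks),
and the one-sided binomial tail on the observed count is
Bonferroni-corrected across the 24 profiles.

Enhancer-vs-promoter variability is compared with a one-sided Mann–Whitney U
on per-peak variances of group means — rank-based, consistent with the
saturated floating-point p-values such comparisons produce at scale.

## Motif analysis

Scan windows are summit ± 100 bp (the flank is configurable; a ±100
interpretation of "100 bp around the summit" was adopted). Scoring is
log₂(p/bg) summed per position with a probability floor of 10⁻³, both
strands; a hit needs ≥ 80 % of the motif's maximum achievable score.
Enrichment is ZOOPS (a sequence counts once): hypergeometric upper tail on
target-with-hit vs all-with-hit, BH across motifs, with the observed
background set (not GC-matched resampling) as the universe. For heatmap-style
outputs, −log₁₀ p rows are Z-scored with the sample SD (floor 10⁻¹²), and
motifs cluster by 1 − Pearson distance with average linkage, deterministic
leaf order, exportable as Newick.

## Region-to-gene association

Basal regulatory domains span 5 kb upstream / 1 kb downstream of each TSS,
strand-aware. A peak overlapping any basal domain is assigned to all those
genes; otherwise it goes to the single gene with the nearest TSS (midpoint
anchor) within 1 Mb, ties to the lower gene coordinate. Term
over-representation is a hypergeometric upper tail per term with BH control;
the recommended universe is all genes carrying at least one annotation.

## Expression, phenotypes, and networks

FPKM = count / (length in kb × mapped reads in millions). The
differential-expression filter is defined here (the upstream study used an
external tool whose model is not re-implemented): genes with missing values
are dropped, log₂FC = log₂((mean_B + 1)/(mean_A + 1)), p from a two-sided
Welch t on log₂(FPKM + 1), and a gene passes at linear fold change ≥ 2
(|log₂FC| ≥ 1) with p < 0.05. On label-permuted null data the pass rate stays
at the α level (tested ≤ 7 % over 20 seeds).

Phenotype formulas: dressing % = carcass/live × 100; thawing and cooking
loss = relative weight loss × 100; the diet NFC/NDF ratio is reported to two
decimals like the composition table. QC summaries use half-up rounding to
two decimals, matching printed-table precision.

Gene–trait networks use Spearman's rank correlation (average ranks for
ties) — rank-based association is the primary choice for small-n phenotype
data; Pearson is available by flag. With n ≤ 8 paired samples the p-value is
exact by full permutation enumeration; larger n uses the t approximation.
BH runs across all gene × trait pairs and edges require q < α. Trait–trait
structure is summarized with a Pearson correlation matrix.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: three ordered
diet groups, two replicates per group for each of ATAC and H3K27ac, a
two-chromosome 10-Mb genome with 400 genes and 600 planted regulatory sites
(half promoter-proximal, half > 10 kb from any TSS), negative-binomial RNA
counts for nine samples, and phenotype traits tied monotonically to
designated genes. Defaults are desk-scale choices a workstation can run in
under a minute; nothing about them encodes expected outcomes.

Key planted structure:

- **Trends.** Enhancer sites split evenly into up (fold enrichment 4→10→24
  over L→M→H), down (mirrored) and flat (12×); promoter-proximal sites are
  flat — promoters are the stable class by design. Each site also carries a
  lognormal (σ = 0.6) baseline multiplier shared across groups and
  replicates: real peak strengths span orders of magnitude, and without this
  shared component replicate score ranks would be uncorrelated and IDR would
  correctly reject everything.
- **Irreproducibility.** A fraction 1 − π₁ (default 10 %) of sites emit
  signal in only the first replicate of each group; these are what the IDR
  stage is supposed to remove, and they cap end-to-end recovery accordingly.
- **Fragments.** Poisson background at 0.02 fragments/bp/sample plus
  site-local pileups (Gaussian around the summit, lognormal replicate jitter
  σ = 0.15); fragment length fixed at 100 bp — read-level details are
  irrelevant post-alignment.
- **Sequence.** I.i.d. bases at configurable GC; the known motif's consensus
  is inserted within summit ± 100 bp of 90 % of up-trending sites on a random
  strand, among ten decoy PWMs that are never planted.
- **Expression/traits.** Genes nearest to up/down enhancers get fold changes
  (1, 2, 4)/(1, ½, ¼) across groups; each linked trait is an affine function
  of its gene's expression plus Gaussian noise with a chosen sign.

All generators are pure functions of (config, seed); per-stage substreams are
derived from the single seed so stages rerun independently and byte-
identically.

What the generator does **not** emulate — and what passing tests therefore do
not show about real data: mappability and GC biases, duplicate reads and
PCR artifacts, fragment-size distributions, copy-number and batch structure,
overlapping/nested genes and alternative TSSs, motif co-occurrence and
flanking-sequence preferences, and biological replicate correlation beyond
the planted shared strengths. Recovery rates on this generator are a
correctness check of the machinery, not a sensitivity claim for any assay.

## Degenerate inputs and tie-breaking (summary)

Constant coverage tracks yield no peaks; all-equal replicate scores are an
error for IDR (no ranking information); all-zero sample columns are an error
naming the sample; flat log₂FC series are excluded from profile assignment;
zero-variance vectors are omitted from correlation networks with a warning.
Ties break deterministically everywhere: leftmost summit, smaller profile id,
lower coordinate, lexicographic ids.

## Problem sizes

Defaults used by the shipped analyses: simulations at 2 × 5 Mb / 600 sites
for the end-to-end run; IDR recovery at n = 2000 pairs per grid cell;
peak-caller calibration on 20 × 2000-bin background tracks; oracle
equivalences at N ≤ 30 (hypergeometric), ≤ 100 genes (assignment) and 30
peaks (profile expectations). These sizes were chosen so the full validation
battery completes in a few minutes on a single CPU while leaving each
statistical check adequately powered.

## Known limitations

- The peak caller's single global λ ignores local background variation;
  copy-number-like artifacts would inflate calls on real data.
- The IDR fit assumes a single reproducible component; graded reproducibility
  (e.g. assay-specific subpopulations) is not modeled.
- Profile templates cover three ordered conditions only.
- The DE statistic is a defined stand-in, not a negative-binomial model; at
  n = 3 per group its power is limited and its null calibration, not its
  optimality, is what is tested.
- GFF3 parsing covers gene features with `ID=` attributes (plus optional exon
  structure supplied programmatically), not the full GFF3 specification.
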