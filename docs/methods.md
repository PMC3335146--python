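# Methods

## The system being modeled

*Caenorhabditis elegans* is androdioecious: hermaphrodites self-fertilize
or outcross with males (X0; hermaphrodites and females are XX), and
hermaphrodites cannot mate with each other. Experimental populations with
standing genetic diversity are built by a *funnel cross*: 16 wild
isolates are combined pairwise into 2-isolate hybrids, those pairwise
into 4-isolate hybrids, and so on until a single 16-isolate hybrid
population exists. A dioecious (obligately outcrossing) counterpart is
derived by recurrent introgression of *fog-2(q71)*, a recessive allele
that converts hermaphrodites into females. This package simulates those
derivations forward in time, estimates selection coefficients from
observed SNP frequencies by simulation-based maximum likelihood, and
computes the windowed haplotype-diversity, LD and differentiation
statistics used to characterize the resulting populations, together with
the mating-system arithmetic (outcrossing rates from sex ratios).

## Meiosis and reproduction model

Chromosomes are ordered vectors of SNP alleles on a genetic map
(strictly increasing bp, non-decreasing cM, 50 cM total per chromosome).
Meiosis uses full crossover interference: with probability 0.5 a single
crossover occurs, its interval between adjacent markers drawn with
probability proportional to the inter-marker cM distance; the gamete
starts on either homolog with probability 1/2 and switches homolog after
the chosen interval. Markers are never split. A fully linked map (all
inter-marker distances zero) transmits intact homologs; drawing a
crossover explicitly on such a map is an error at the primitive level.

Reproduction is a gamete-pool scheme: each offspring independently
either selfs (with the stage's selfing rate; both gametes from one
weighted hermaphrodite draw) or joins gametes from two independent
weighted parent draws, i.e., sampling with replacement as if gametes are
in large excess relative to the number of reproducing individuals.
Selection enters once per generation, before mating, as the sampling
weight w = 1 + n·s with n the number of copies of the favored allele
(0–2; 0/1 on a hemizygous X). The `core` primitives (`mate`,
`transmit_x`, `self_fertilize`, `next_generation`) model male X
hemizygosity explicitly; the population-scale simulators default to the
all-diploid gamete-pool simplification, which matches the pool
description above and differs from the hemizygous model only in X-linked
dosage bookkeeping. Females appear only in dioecious populations,
hermaphrodites only in androdioecious ones.

## Funnel-cross and introgression simulation

One hybridization cycle comprises a cross phase — reciprocal F1 crosses,
two generations of within-lineage intercrossing (F2, F3), and an F4
merge of the reciprocals — followed by an expansion phase of 2–4
generations (default 3) at large size with selfing rate 0.5. Defaults:
10 hermaphrodites per cross-phase generation, 20 at the F4 merge, 10^3
individuals per expansion generation; every size is a config value. A
2^k-isolate funnel runs k cycles down a balanced pairing tree.

Two engines implement the same model:

* an **array engine** tracking full haplotypes (`(n, 2, L)` arrays per
  chromosome, vectorized meiosis), used wherever linkage matters
  (envelopes over all SNPs, regional compound likelihoods, LD and
  haplotype statistics on simulated populations);
* a **single-locus count engine** tracking only the three genotype
  classes at one marker. Conditional on the parent generation, offspring
  genotype counts are Multinomial(n, π) with π computed exactly from the
  weighted genotype distribution (selfing via the Mendelian table,
  outcrossing via random union of two weighted gametes), so the engine
  is distributionally identical to the array engine at a single marker
  (checked by a test comparing the two); it is used for the likelihood
  grid, where ~10^6 replicate funnels are needed.

Introgression cycles cross donor-homozygous females to recipient males,
self the F1, and retain F2 individuals homozygous for the donor allele
at the focal locus (genotype-based truth selection; phenotypic scoring
error is not modeled). Cycle sizes default to the study design (8 cycles
of 53 females, one of 105, a final 199). The expected donor-genome
fraction at unlinked markers halves per cycle (2^-t), which the tests
verify.

## Selection inference

The selection coefficient at a focal SNP is estimated on a grid of 101
points (s = 0 to 1, step 0.01). For each grid point the derivation is
simulated repeatedly and the binomial likelihood
Binom(obs | 2N_sample, f_sim) of the observed allele count is evaluated
against each simulated final frequency. The per-point likelihood is the
*mean of per-simulation likelihoods* (an estimate of the marginal
P(obs | s) that respects multimodal final-frequency distributions); the
alternative — the likelihood at the mean simulated frequency — is
available as `likelihood_mode="lik_of_mean"`. Simulated frequencies are
clamped half a chromosome count away from 0 and 1 so the surface is
finite everywhere. Argmax ties break toward smaller s. Significance
against s = 0 is a likelihood-ratio test on χ²(1); because s = 0 is a
boundary the reference distribution is conservative (a mixture would be
exact), which is documented rather than corrected. Replicated estimation
uses keyed RNG substreams per replicate, either re-estimating a fixed
observation (the precision of one estimate) or redrawing a fresh
pseudo-observation per replicate (parameter recovery).

The observed sample defaults to 2 × 89 chromosomes (89 genotyped
diploids). Regional evidence over a marker set sums per-marker log10
likelihoods (a compound likelihood) computed from joint multi-marker
simulations that include recombination, under two scenarios (e.g.,
neutral vs. selected) for comparison.

Known property: with fresh pseudo-observations per replicate, the
distribution of grid ML estimates at moderate truth values is
right-skewed under heavy derivation drift — observations near fixation
drive estimates toward 1 while the s = 0 boundary cannot compensate —
so the replicate *mean* sits above the truth (at truth 0.53 with the
default stage sizes, the large-simulation limit of the replicate mean is
≈ 0.60 with median ≈ 0.54). Re-estimating a fixed observation does not
show this effect; its replicate spread reflects only simulation noise.

## Windowed diversity statistics

Genotype QC applies three sequential missing-data filters: SNPs with
missing fraction > 0.8; individuals with missing fraction > 0.5;
individuals above the 95% quantile of the remaining missingness
distribution (an empirical upper-tail rule; with a flat distribution —
e.g., no missing data — nothing is removed). LD uses Burrows' composite
disequilibrium from unphased dosages, Δ = Σxy/(2n) − 2p_i p_j and
r² = Δ²/(p_i q_i p_j q_j), after removing markers with MAF < 0.05 in
either population; simulated haplotypes are collapsed to unphased
genotypes before LD is computed so observed and simulated estimators
match. Haplotype statistics slide windows of 2/5/10 SNPs with step 1,
anchored at the mean bp of the window's markers: distinct-string counts,
the fraction of distinct strings matching a parental panel, the shared
fraction |A∩B|/|A∪B|, and a multi-allelic FST on window-haplotype
frequencies (Nei-style G_ST with sample-size-weighted within-population
heterozygosity; FST = 0 when H_T = 0; clipped to [0, 1]). Windows with
missing alleles use complete haplotypes only and are undefined (NaN)
rather than zero when fewer than two remain. Significance thresholds
come from reshuffling marker columns within a chromosome (same
permutation in both populations, individuals never permuted; default
10^4 permutations) and pooling window values chromosome-wide to take the
95% quantile. Density-matched jackknifing draws order-preserving marker
subsets (e.g., 179 or 199 markers) from a denser reference panel and
recomputes window counts per draw.

## Mating-system analytics

Under androdioecy with a 1:1 outcross sex ratio, the outcrossing rate is
t = 2m (m = male frequency), reported to two decimals. Because males are
undercounted in plate assays (they are harder to identify and flee to
plate edges), the male frequency observed in a dioecious control — truly
0.5 — calibrates a detectability factor c = observed/0.5 (0.37/0.5 =
0.74 in the study system), and the corrected rate is min(1, 2m/c).
Expected homozygosity from a fully heterozygous base is 1 − (1/2)^t
under selfing and follows H_t = H_{t−1}/2 + H_{t−2}/4 (H_0 = H_1 = 1,
an outbred founding pair) under full-sib mating; both derivation schemes
(11 generations selfing, 22 sib-mating) exceed 98% homozygosity.
Selection-mode tests use Pearson correlations with one-sided Student t
tests on n − 2 df; sex-ratio deviation uses a 1-df χ² against 1:1;
X-non-disjunction male production is summarized as a pooled proportion
with an exact binomial interval.

## Synthetic data

The generator emulates the study's data shapes with known truth: maps
with five recombination-rate domains (telomere caps at 0.1 cM/Mb, arms
and center at 7.65/1.05/3.64 cM/Mb for chromosome IV and 3.81/1.7/5.14
for X, domain fractions 2/20/56/20/2% of 17.5 and 17.7 Mb — round
figures chosen so each chromosome integrates to under 50 cM); panels of
16 homozygous isolates carrying exactly 14 distinct genotypes built as
random block mosaics (marginal frequencies and the distinct-genotype
count are what matter downstream; no coalescent ancestry is claimed),
with every SNP polymorphic in the panel; observed-style samples of 89/90
diploids with independent missing calls; and plate censuses with
Poisson totals where each true male is scored with a detection
probability and misses are tallied as non-males. Synthetic data carry
none of real data's genotyping-error structure, linkage-informed allele
sharing, or phasing uncertainty, so passing tests demonstrate correct
computation on the stated model, not robustness to those artifacts.

## Numerical and design choices

* RNG: numpy `SeedSequence` keyed by (seed, string/int keys); replicates
  and stages get independent, reproducible substreams.
* Frequencies are computed over all segregating chromosomes (2 per
  diploid, 1 per hemizygous male X in core).
* Envelopes are pointwise per-SNP empirical (α/2, 1−α/2) quantiles and
  require ≥ 40 simulations; on distributions with atoms (e.g., allele
  loss mass at 0) a closed empirical interval over-covers the nominal
  level — a property of discrete data, visible when envelope coverage is
  checked against funnels with many founders.
* Negative Δ²-derived quantities and FST round-off are clipped to 0;
  composite r² is clipped to 1.
* The three-step QC order is fixed (SNPs, then individuals, then the
  upper tail) and the filter is idempotent.
* Test and demo problem sizes (founder counts of 2–4, expansions of
  60–120, dozens of SNPs) are chosen so each check isolates one property
  at Monte-Carlo tolerances of 3 standard errors; the selection-recovery
  checks use the full study-scale design (16 founders, 10^3 expansions,
  101-point grid).

## Limitations

Haplotype phasing is out of scope (the pipeline consumes phased inputs
or simulation truth). No mutation, no multiple crossovers, no
overlapping generations, no demographic stochasticity in stage sizes.
The χ²(1) reference for the boundary LRT is conservative. The funnel
cross-phase sample sizes are config defaults, not transcribed study
values; inference results depend on them through the drift they impose.
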