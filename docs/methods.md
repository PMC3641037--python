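# Methods

## The analysis chain

The package implements the statistical chain used in landscape-scale
phylogeographic surveys that combine a multilocus dominant-marker table
(AFLP band presence/absence) with a single mitochondrial coding locus:

1. genetic distances (Jaccard for bands, pairwise ML GTR+Γ for sequences,
   great-circle km for coordinates);
2. model-based clustering with admixture and the Evanno ΔK criterion, plus a
   model-free cross-check (non-metric MDS + Gaussian mixture by BIC);
3. ANOSIM tests of the geographic coherence of the inferred clusters;
4. a dbRDA variance partition separating isolation by distance (IBD) from
   cluster subdivision;
5. a descriptive quartile screen for barrier-spanning and
   long-distance-dispersal (LDD) pairs;
6. Fu's Fs and McDonald–Kreitman neutrality tests on the sequence data;
7. a per-locus logistic environmental-association scan.

## Models and estimators

### Admixture model for dominant markers

Bands are haploid Bernoulli characters: cluster k has band frequency
`p_kl ~ Beta(1,1)`; individual i has admixture vector
`q_i ~ Dirichlet(α·1_K)` (α = 1 by default, switchable); each call picks a
source cluster `z_il ~ Cat(q_i)` and then `x_il ~ Bernoulli(p_{z_il,l})`.
This deliberately ignores the diploid dominant-genotype likelihood (band
absence = recessive homozygote): with band frequencies free per cluster, the
cluster memberships and the chosen K — the quantities this chain consumes —
are driven by between-cluster frequency contrasts, which the Bernoulli model
captures; the absolute log-marginal-likelihood values are not comparable to
diploid-model software and are not used as such.

All full conditionals are conjugate and the sampler is plain Gibbs, run in
float32 (the likelihood trace enters only via across-sweep means and
variances, far above float32 noise). Chains warm-start from a k-means hard
clustering whose seed depends only on the data and K: replicate runs then
share a starting mode and their spread reflects Monte-Carlo noise rather
than an initialisation lottery; plain prior-draw initialisation is available
(`init="random"`) and occasionally sticks in empty-cluster modes.

The per-run model score is `mean(lnL) − var(lnL)/2` over post-burn-in
sweeps. ΔK(K) divides the absolute second difference of the per-K mean score
by the across-run standard deviation at K; the mean-of-per-run-second-
differences variant is exposed as an option. ΔK is undefined at the grid
ends; zero run variance yields an infinite sentinel with a warning.

Multi-run protocol: ΔK is a ratio of curvature to run spread, so it is most
stable with *many short* runs — with few long runs the tiny Monte-Carlo
spread makes the denominator a lottery. The defaults used in the tests and
the acceptance run (12 runs per K, 100 burn-in + 60 recorded sweeps, K in
3..7) were chosen on that ground.

### Distances

Jaccard: `d = 1 − a/(a+b+c)` over loci observed in both individuals; a pair
sharing no scored band gets distance 0 with a warning. Geographic distances
default to great-circle on a spherical earth (R = 6371.0088 km); the
equirectangular alternative differs by < 0.5% at a ~260 × 60 km island
extent, so the projection choice is immaterial at this scale. GTR+Γ
distances are pairwise maximum-likelihood branch lengths under a single
model fitted to the whole alignment: empirical base frequencies, five free
exchangeabilities (r_GT ≡ 1) and the gamma shape (4 mean-discretised
categories) maximising the composite pairwise log-likelihood, alternating
bounded Nelder–Mead over log-parameters with per-pair branch-length updates.
Box bounds (log-scale ±3.5) exclude the flat extreme corners of the
composite likelihood. Pairs with fewer than 50 jointly resolved sites are
reported as missing.

### ANOSIM, dbRDA

ANOSIM uses mean ranks for ties and the permutation estimate
`p = (1 + #{R* ≥ R}) / (1 + B)`; pairwise tests Bonferroni-correct over the
number of testable pairs, skipping singleton groups. dbRDA follows
McArdle–Anderson: `G = J(−½D²)J`, pseudo-F from traces of `HGH` and
`(I−H)G(I−H)`; negative eigenvalues of G (expected for Jaccard) stay in the
traces and their share is reported as a diagnostic. With covariates Z, X is
residualised on [1 Z], the denominator uses the full [Z X] fit, and
permutations shuffle the residualised predictors (Freedman–Lane style; raw
permutation is available since distance-based-linear-model implementations
differ and the choice is not standardised). A saturated permuted fit (zero
residual trace, possible when G has low rank at small n) maps to an infinite
pseudo-F rather than an error. The IBD-vs-subdivision report runs (i) D ~
lat+lon, (ii) D ~ cluster dummies | lat+lon, (iii) per-cluster D ~ lat+lon,
skipping clusters with n < 4 (degrees-of-freedom exhaustion).

Geographic predictors are latitude and longitude in decimal degrees — at the
emulated extent the difference from projected km coordinates is a near-affine
rescaling that leaves the tests essentially unchanged.

### Quartile screens

Thresholds are nearest-rank percentiles with inclusive comparisons
(deterministic under ties; tie counts are reported); linear-interpolation
percentiles are an option, since reported pair counts can hinge on the
convention. Barrier pairs: genetic ≥ Q3 and geographic ≤ Q1; LDD pairs:
genetic ≤ Q1 and geographic ≥ Q3. The screen is descriptive — no
significance test is attached, and quartiles are computed over all pairs
without stratification.

### Fu's Fs and McDonald–Kreitman

`S′ = P(K ≥ k_obs | θ = θ̂_π)` under the Ewens sampling formula (unsigned
Stirling numbers of the first kind built by the log-space recurrence);
`Fs = ln(S′/(1−S′))`. Haplotypes are exact sequence matches after removing
alignment columns containing any gap; ambiguity codes count as mismatches.
θ̂_π uses all sites by default; a third-codon-position variant
(`theta_sites="third_positions"`) is available as a silent-site proxy, since
sequence-statistics packages differ on this convention. The p-value is one-tailed left — Fs is an expansion
statistic — from neutral constant-size infinite-sites coalescent replicates
(msprime; haploid samples, N = 1, mutation rate θ/2 per coalescent time
unit, so E[π] = θ), each replicate re-estimating θ from its own π.

MK counts synonymous/nonsynonymous changes among ingroup-polymorphic codons
and strictly fixed differences (both groups monomorphic; outgroup-polymorphic
codons excluded). Two-state codons differing at several positions are scored
by enumerating minimal mutational pathways, discarding paths through stops
and averaging; codons with more than two ingroup states or any gap/N are
excluded and logged. The 2×2 table is tested with the standard two-sided
Fisher exact test (genetic code: NCBI table 5, invertebrate mitochondrial,
configurable).

### Environmental scan

Each (locus, variable) pair gets a two-parameter logistic regression fitted
by batched Newton iterations on the standardised variable. A locus is called
only when both the likelihood-ratio G and the Wald W fall below
`(1 − confidence)/n_tests` (Bonferroni; n_tests counts attempted pairs by
default, completed-only as an option, both logged). Complete or
quasi-complete separation is detected (diverging slope, failed convergence
or singular information) and flagged, not penalised — the test definition
stays plain logistic regression.

## The synthetic-data generator

`SimulationConfig` defaults emulate the motivating survey: 95 individuals at
84 localities on a 260 × 60 km map split into 5 contiguous regions by
north-south barriers, 1328 binary loci, a 633-bp coding locus with two
outgroup sequences, ~105-variable-style smooth environmental surfaces
reduced to 8 representative variables.

- Latent band frequencies are Beta(0.5, 0.5): the U-shape mimics
  dominant-marker spectra and maximises per-locus cluster information.
- IBD enters as a linear drift of band frequency with distance from the
  cluster centroid (default 0.002 per km with a random per-locus sign).
- Individuals within 15 km of a barrier get linearly mixed ancestry.
- LDD is relocation: the genotype travels, genes do not blend (passive
  transport), at rate 0.05 per individual.
- Sequences descend from per-cluster msprime genealogies. `growth_factor` is
  the fold expansion of each cluster population over the recent past
  (present size F collapsing to 1 by half the split time); large F
  concentrates coalescence at the collapse and yields the long-tipped star
  genealogies of an expansion, F ≤ 1 is constant size. Mutations are placed
  by the package itself with transition bias κ = 4; candidate nonsynonymous
  changes are accepted with probability ω = 0.2 *on every branch alike*, so
  the McDonald–Kreitman null holds by construction. Defaults θ = 40,
  F = 100, splits at 0.5 / 1.5 coalescent units give many unique haplotypes
  over a deep cluster structure — the expansion regime the chain is meant to
  detect.
- All randomness flows from one seed through named, CRC-keyed
  `SeedSequence` spawns; identical configs reproduce outputs byte for byte.

Not emulated: migration during coalescence, recombination, indels, marker
ascertainment (a drop-monomorphic switch is provided instead of guessing),
spatial autocorrelation of residual noise, and raster output. Consequently,
passing tests show that the estimators recover the signals the generator
plants under clean assumptions; they do not certify behaviour under
ascertainment bias or fine-scale spatial autocorrelation in real AFLP data.

A consequence worth knowing: with the full 5-cluster structure, smooth
environmental surfaces correlate with cluster membership, and the
environmental scan flags many loci that are spatially confounded rather than
selected — the known weakness of univariate association scans without
population-structure correction. The scan's power and false-positive
behaviour are therefore measured on a single-cluster background (no
confounding), and the structured-background count is reported as what it is.

## Problem sizes and numerical choices

Tests and the acceptance run scale the marker count to 600 of the default
1328 loci for the admixture K-grid (the chain cost is linear in loci;
recovery is already reliable at 600) and use 999–9999 permutations and 1000
coalescent replicates; these sizes are the package's chosen defaults for a
routine desktop run. Permutation p-values use the +1 correction and are
never exactly zero. Degenerate inputs (identical sequences, all-zero
distance matrices, saturated permuted fits, single-haplotype samples,
zero-variance ΔK denominators) return documented sentinels or errors rather
than silent numbers.

Stage-level result caching was considered and rejected: every stage at
package scale runs in seconds-to-minutes, and content-hash invalidation
would add more failure surface than it saves.
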