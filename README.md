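# phylogeokit

Phylogeographic analysis of dominant-marker (AFLP) datasets paired with a
mitochondrial coding alignment — the analysis chain used to ask how a
widespread, poorly dispersing species (the motivating case is a land snail on
an elongated Mediterranean island) is structured: are populations subdivided
by barriers into genetic clusters, do they show isolation by distance within
clusters, has the species expanded recently, and does the environment leave a
detectable selective footprint on individual loci?

The package is aimed at population geneticists working with binary
presence/absence markers (AFLP band tables) plus a single-locus sequence
alignment, and provides:

- **Admixture clustering** of binary markers by Gibbs sampling of the model
  `x_il ~ Bernoulli(p_{z_il,l})`, `z_il ~ Categorical(q_i)`,
  `q_i ~ Dirichlet(α)`, `p_kl ~ Beta(1,1)`, with the Evanno
  **ΔK = m(|L(K+1) − 2L(K) + L(K−1)|) / s[L(K)]** criterion for the number of
  clusters, and a model-free cross-check (non-metric MDS of Jaccard distances
  plus a BIC-selected Gaussian mixture).
- **ANOSIM** (global and pairwise with Bonferroni correction):
  `R = (r̄_B − r̄_W) / (M/2)` on ranked distances, permutation p-values.
- **Distance-based RDA** (McArdle–Anderson): pseudo-F on the Gower-centred
  inner-product matrix, with covariates (partial dbRDA, Freedman–Lane
  permutation) to separate isolation by distance from cluster subdivision.
- **Barrier / long-distance-dispersal screens**: individual pairs jointly in
  the extreme quartiles of genetic and geographic distance, exported as TSV
  and GeoJSON lines.
- **Sequence tests**: Fu's Fs via the Ewens sampling formula (log-space
  Stirling numbers) with a coalescent-simulation p-value, and the
  McDonald–Kreitman test with minimal-pathway codon counting.
- **Environmental association scan**: per-locus logistic regressions against
  environmental variables, gated on *both* the likelihood-ratio G and Wald
  tests under Bonferroni correction.
- **Distances**: Jaccard (with pairwise deletion of missing bands),
  great-circle / equirectangular geographic distances, and pairwise
  maximum-likelihood GTR+Γ distances for the sequence data.
- **A spatially explicit simulator** that generates marker matrices,
  coordinates, environmental surfaces and coding alignments with all of the
  above signals under known truth — every stage is testable without field
  data.

## Worked example

```python
from phylogeokit import (
    SimulationConfig, simulate_dataset, jaccard_matrix, geographic_matrix,
    AdmixtureModel, delta_k, anosim, dbrda, screen_pairs, fu_fs,
)
from phylogeokit.admixture import run_k_grid
from phylogeokit.ordination import ClusterAssignment

bundle = simulate_dataset(SimulationConfig(n_loci=600, seed=1))
markers, samples = bundle["markers"], bundle["samples"]

d_gen = jaccard_matrix(markers)
d_geo = geographic_matrix(samples)

log, fits = run_k_grid(markers, 3, 7, n_runs=12, burn_in=100, sweeps=60, seed=1)
dk = delta_k({k: g["model_lnp"].tolist() for k, g in log.groupby("K")})
print("best K by delta-K:", dk.best_k)

labels = ClusterAssignment.from_array(
    markers.individual_ids,
    max(fits[dk.best_k], key=lambda r: r.model_lnp).hard_assignment(),
)
print(anosim(d_geo, labels, seed=1).summary())
print(dbrda(d_gen, samples.coordinates(), n_permutations=999, seed=1).summary())
print(screen_pairs(d_gen, d_geo, "ldd").summary())
print(fu_fs(bundle["alignment"], seed=1).summary())
```

prints (seed 1):

```
best K by delta-K: 5
ANOSIM: R = 0.7852, p = 9.999e-05 (10000 permutations, n = 95)
dbRDA: pseudo-F = 8.9340, p = 0.001, proportion explained = 0.1626 (n = 95, m = 2, predictors: ['x1', 'x2'])
ldd screen: 76 of 4465 pairs flagged (genetic threshold 0.590278, geographic threshold 136.133 km)
Fu's Fs: n=95, k=95, theta_pi=16.0739, Fs=-118.7348, p=0.000999 (1000 coalescent simulations)
```

Read: the simulated survey is recovered as five clusters (ΔK), the clusters
are geographically coherent (ANOSIM R ≈ 0.79), isolation by distance explains
a significant but small share of genetic variation (≈ 16%), 76 individual
pairs look like long-distance dispersal, and the strongly negative Fu's Fs
flags the simulated population expansion.

The same chain runs from the shell:

```bash
phylogeokit simulate --seed 1 --out data/
phylogeokit all --config config.yaml --out results/
```

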