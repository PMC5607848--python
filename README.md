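# straindec

De novo resolution of strain-level haplotypes, per-sample strain
frequencies and strain-specific gene complements from multi-sample shotgun
metagenome data.

## The problem

A metagenome-assembled genome (MAG) is a species-level composite: the reads
that built it usually come from several closely related strains whose
mixture varies across samples. `straindec` exploits exactly that variation.
Given per-position base counts n_{v,s,a} (position v, sample s, base
a ∈ {A,C,G,T}) on the MAG's single-copy core genes, it

1. **detects variant positions** with a likelihood-ratio test — at each
   position the null "one true base observed through a 4×4 error matrix ε"
   is tested against "two bases at consensus frequency p", with
   −2 log(H₀/H₁) referred to χ²(1), ε re-estimated iteratively from
   non-variant positions, and Benjamini–Hochberg FDR control;
2. **deconvolves haplotypes**: counts at variant positions are modelled as
   multinomial draws from Σ_g Σ_b τ_{v,g,b} π_{g,s} ε_{b,a}, where
   τ_{v,g,·} is the one-hot base of strain g and π_{·,s} the strain
   proportions in sample s. A collapsed-free Gibbs sampler with conjugate
   Dirichlet updates (via auxiliary count allocations ν and ξ) samples
   (τ, π, ε); it is initialised by a non-negative tensor factorisation of
   the base proportions. The strain number G is chosen by posterior-mean
   deviance drops plus replicate reproducibility;
3. **assigns the accessory genome**: each gene's presence η_{f,g} ∈ {0,1}
   per strain is inferred from a Poisson coverage model
   x_{f,s} ~ Pois(Σ_g η_{f,g} π_{g,s} Y_s) combined with the multinomial
   variant model restricted to carrying strains;
4. **summarises strain divergence** as
   d = 1 − Σ_c min(υ_g, υ_h)/Σ_c max(υ_g, υ_h) over gene-cluster profiles.

A simulator module generates ground-truthed communities (log-normal
species abundances, Dirichlet strain proportions, Poisson coverages,
multinomial base counts) from the model's own forward process, so every
stage is testable without external data.

## Worked example

```python
import numpy as np
from straindec import gibbs_run, match_haplotypes, seed_error_matrix
from straindec import simulate as sim

rng = np.random.default_rng(11)
G, S, V = 3, 20, 150
pi = sim.dirichlet_frequencies(G, S, rng)        # true strain fractions
tau = sim.random_haplotypes(V, G, rng)           # true bases per strain
tensor = sim.simulate_variant_tensor(tau, pi, seed_error_matrix(0.995), 50, rng)

chain = gibbs_run(tensor, G, burn=100, samples=100, seed=11)
perm, hamming = match_haplotypes(tau, chain.tau_map)
print(np.round(100 * (1 - hamming), 2))          # [100. 100. 100.]
print(round(float(np.sqrt(((pi - chain.pi_mean[perm])**2).mean())), 4))  # 0.0049
```

All 150 variant bases of each of the three strains are recovered exactly
(100% per-strain accuracy after optimal label matching) and the inferred
per-sample strain frequencies match the simulated ones to RMSE 0.005.
The `examples/` directory has one short script per capability (variant
detection, deconvolution, strain-number selection, gene content, genome
divergence); each prints the numbers it computes and what they mean.

A thin CLI mirrors the stages:

```bash
straindec simulate -g 3 -s 20 -n 500 --out sim/
straindec variants sim/base_counts.tsv --out calls/
straindec haplotypes sim/base_counts.tsv --g-max 5 --out haps/
```

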