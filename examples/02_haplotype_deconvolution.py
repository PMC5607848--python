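"""Deconvolve a variant tensor into strain haplotypes and frequencies.

Draws a V x S x 4 base-count tensor from the multinomial mixture model
(3 strains, 20 samples), then runs the NTF-initialised Gibbs sampler at
the true strain number and scores the recovery.
"""

import numpy as np

from straindec import gibbs_run, match_haplotypes, seed_error_matrix
from straindec import simulate as sim

rng = np.random.default_rng(11)
G, S, V = 3, 20, 150
eps = seed_error_matrix(0.995)
pi = sim.dirichlet_frequencies(G, S, rng)  # per-sample strain proportions
tau = sim.random_haplotypes(V, G, rng)  # true base per strain per position
tensor = sim.simulate_variant_tensor(tau, pi, eps, mean_depth=50, rng=rng)

chain = gibbs_run(tensor, G, burn=100, samples=100, seed=11)

perm, hamming = match_haplotypes(tau, chain.tau_map)
print(f"variant positions:        {V}")
print(f"posterior mean deviance:  {chain.posterior_mean_deviance(tensor):.1f}")
print(f"per-strain SNV accuracy:  {np.round(100 * (1 - hamming), 2)} %")
print(f"frequency RMSE:           {np.sqrt(((pi - chain.pi_mean[perm]) ** 2).mean()):.4f}")

# accuracies near 100% mean each inferred haplotype matches a distinct true
# strain after optimal label matching; the RMSE compares inferred per-sample
# strain frequencies with the simulated ones.
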