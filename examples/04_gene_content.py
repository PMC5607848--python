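"""Infer which strain carries which accessory gene.

Simulates 300 genes with random per-strain presence, Poisson coverages
(superposition of the carrying strains' coverages) and variant positions
from the carrier-renormalised multinomial model, then runs the NMF-seeded
presence/absence Gibbs sampler with the strain frequencies held fixed.
"""

import numpy as np

from straindec import eta_gibbs, seed_error_matrix, strain_coverage
from straindec import simulate as sim

rng = np.random.default_rng(31)
F, G, S = 300, 4, 32
eps = seed_error_matrix(0.995)
pi = sim.dirichlet_frequencies(G, S, rng)
Y = rng.uniform(20, 50, size=S)  # total core coverage per sample
gamma = strain_coverage(pi, Y)  # per-strain coverage
truth = sim.simulate_gene_truth(F, G, rng, presence_prob=0.7)
x, m = sim.simulate_gene_data(truth, gamma, pi, eps, rng)

res = eta_gibbs(m, x, pi, eps, gamma, burn=20, samples=20, seed=31)

acc = (res.eta_call == truth.eta).mean()
print(f"genes: {F}, strains: {G}, samples: {S}")
print(f"per-cell presence/absence accuracy: {100 * acc:.2f} %")
print(f"genes called in every strain:       {(res.eta_call.sum(axis=1) == G).sum()}")
print(f"genes called absent everywhere:     {(res.eta_call.sum(axis=1) == 0).sum()}")

# each cell of the genes x strains matrix is a presence call; accuracy is
# the fraction of cells matching the simulated gene complement.
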