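"""Detect variant positions on core genes with the likelihood-ratio test.

Simulates aggregated base counts for a 3-strain population (mostly
invariant positions plus planted variants), then runs the iterated
error-matrix estimation with Benjamini-Hochberg FDR control.
"""

import numpy as np

from straindec import fit_error_matrix, seed_error_matrix
from straindec import simulate as sim

ds = sim.simulate_variant_detection_dataset(
    n_invariant=5000, n_variant=500, G=3, S=24,
    mean_depth_per_sample=10.0, eps_diag=0.995, seed=7,
)

result = fit_error_matrix(ds.counts, p_min=0.01, fdr=1e-3)
called = result.is_variant
tp = (called & ds.is_variant).sum()

print(f"positions tested:      {len(ds.counts)}")
print(f"variants called:       {called.sum()}")
print(f"recall:                {tp / ds.is_variant.sum():.3f}")
print(f"precision:             {tp / called.sum():.3f}")
print(f"refinement iterations: {result.n_iterations}")
print("fitted error-matrix diagonal:", np.round(np.diag(result.error_matrix), 4))

# recall/precision near 1 show the chi-squared LR test separates true
# mixed-base positions from sequencing error at this depth; the fitted
# diagonal should sit near the simulated per-base fidelity of 0.995.
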