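"""Pairwise genome divergence between inferred strains.

Each strain is summarised as a vector of gene-cluster frequencies υ_{g,c}
(clusters of near-identical gene sequences). Divergence between strains g
and h is one minus the ratio of summed element-wise minima to maxima:

    d_{g,h} = 1 − Σ_c min(υ_{g,c}, υ_{h,c}) / Σ_c max(υ_{g,c}, υ_{h,c}),

which is 0 when the strains share all gene clusters and 1 when they share
none. A deliberately simple greedy equal-length identity clustering is
provided for synthetic genes; real analyses should supply externally
computed gene → cluster tables.
"""

from __future__ import annotations

import numpy as np


def genome_divergence(v_g: np.ndarray, v_h: np.ndarray) -> float:
    """Divergence in [0, 1] between two non-negative cluster-count vectors."""
    v_g = np.asarray(v_g, dtype=float)
    v_h = np.asarray(v_h, dtype=float)
    if v_g.shape != v_h.shape:
        raise ValueError("cluster vectors must have equal dimension")
    if np.any(v_g < 0) or np.any(v_h < 0):
        raise ValueError("cluster counts must be non-negative")
    denom = np.maximum(v_g, v_h).sum()
    if denom == 0:
        raise ValueError("divergence undefined for two all-zero profiles")
    return float(1.0 - np.minimum(v_g, v_h).sum() / denom)


def divergence_matrix(v: np.ndarray) -> np.ndarray:
    """Symmetric strain × strain divergence matrix from profile rows."""
    v = np.asarray(v, dtype=float)
    G = v.shape[0]
    out = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            out[i, j] = out[j, i] = genome_divergence(v[i], v[j])
    return out


def greedy_identity_cluster(sequences: list[str], identity_threshold: float = 0.95) -> list[int]:
    """Greedy centroid clustering of equal-length sequences by identity.

    Sequences join, in input order, the first centroid with Hamming
    identity ≥ threshold; otherwise they found a new cluster. Pairs of
    unequal length never merge. Cluster membership can depend on input
    order (centroids are first members); this is documented behaviour.
    """
    centroids: list[str] = []
    assignment: list[int] = []
    for seq in sequences:
        placed = False
        for c, cen in enumerate(centroids):
            if len(cen) == len(seq):
                ident = sum(a == b for a, b in zip(cen, seq)) / len(seq)
                if ident >= identity_threshold:
                    assignment.append(c)
                    placed = True
                    break
        if not placed:
            assignment.append(len(centroids))
            centroids.append(seq)
    return assignment


def cluster_profiles(assignments_per_strain: list[list[int]]) -> np.ndarray:
    """υ_{g,c} counts from per-strain lists of cluster ids."""
    n_clusters = 1 + max((max(a) for a in assignments_per_strain if a), default=-1)
    out = np.zeros((len(assignments_per_strain), max(n_clusters, 1)), dtype=int)
    for g, assigned in enumerate(assignments_per_strain):
        for c in assigned:
            out[g, c] += 1
    return out
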