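"""Ground-truthed synthetic communities for every inference stage.

The generators implement the exact forward model the inference assumes, at
the base-count tensor level (read simulation, mapping and assembly are
upstream concerns):

* species abundances across samples are normalised log-normals — per
  species t, y_{t,s} ~ Normal(μ_t, σ_t) and n_{t,s} = softmax_t(y_{t,s}),
  with μ_t ~ Normal(1, 0.25) and σ_t ~ Gamma(shape 1, scale 1) by default;
* within-species strain proportions are symmetric Dirichlet (unit vector);
* strain coverage z_{d,s} = R κ_{d,s} N_s / L_d for read length R, reads
  per sample N_s, genome length L_d, strain read fraction κ = n·ρ;
* variant base counts at (v, s) are multinomial over Σ_g Σ_b τ π ε with a
  Poisson-drawn depth;
* gene coverages are Poisson superpositions of the carrying strains'
  coverages, and gene variant counts follow the carrier-renormalised
  multinomial model.

Everything is reproducible from a seed plus the recorded parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variants import seed_error_matrix

DEFAULT_READ_LENGTH = 150  # one mate of a 2×150 bp pair; pairs count as two reads


@dataclass
class CommunityDesign:
    """Parameters of a simulated multi-sample community."""

    strains_per_species: list[int]
    genome_lengths: list[float]  # per strain, bp, flattened over species
    n_samples: int = 64
    reads_per_sample: float = 6.25e6
    read_length: int = DEFAULT_READ_LENGTH
    mu_mean: float = 1.0
    mu_sd: float = 0.25
    sigma_shape: float = 1.0
    sigma_scale: float = 1.0
    dirichlet_a: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.strains_per_species):
            raise ValueError("each species needs at least one strain")
        if len(self.genome_lengths) != sum(self.strains_per_species):
            raise ValueError("one genome length per strain is required")
        if any(l <= 0 for l in self.genome_lengths):
            raise ValueError("genome lengths must be positive")


@dataclass
class AbundanceDraw:
    species_freq: np.ndarray  # (T, S): n_{t,s}, columns sum to 1
    strain_read_fraction: np.ndarray  # (D, S): κ_{d,s}
    strain_coverage: np.ndarray  # (D, S): z_{d,s}
    strain_species: np.ndarray  # (D,) species index of each strain


def simulate_abundances(design: CommunityDesign, rng: np.random.Generator | None = None) -> AbundanceDraw:
    """Draw species/strain abundances and coverages for a community design."""
    rng = rng or np.random.default_rng(design.seed)
    T = len(design.strains_per_species)
    S = design.n_samples
    mu = rng.normal(design.mu_mean, design.mu_sd, size=T)
    sigma = rng.gamma(design.sigma_shape, design.sigma_scale, size=T)
    y = rng.normal(mu[:, None], sigma[:, None], size=(T, S))
    expy = np.exp(y - y.max(axis=0, keepdims=True))
    n_ts = expy / expy.sum(axis=0, keepdims=True)

    D = sum(design.strains_per_species)
    kappa = np.zeros((D, S))
    species_of = np.zeros(D, dtype=int)
    d0 = 0
    for t, n_strains in enumerate(design.strains_per_species):
        rho = rng.dirichlet(np.full(n_strains, design.dirichlet_a), size=S).T  # (strains, S)
        kappa[d0 : d0 + n_strains] = n_ts[t] * rho
        species_of[d0 : d0 + n_strains] = t
        d0 += n_strains

    lengths = np.asarray(design.genome_lengths, dtype=float)
    z = design.read_length * kappa * design.reads_per_sample / lengths[:, None]
    return AbundanceDraw(n_ts, kappa, z, species_of)


def genome_freq_to_coverage(pi_prime: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Relative genome frequencies → relative coverages.

    π_{g,s} = (π′_{g,s}/L_g) / Σ_h (π′_{h,s}/L_h); strains of equal length
    are unchanged.
    """
    pi_prime = np.asarray(pi_prime, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("genome lengths must be positive")
    w = pi_prime / lengths[:, None]
    return w / w.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# variant tensors


def random_haplotypes(
    V: int, G: int, rng: np.random.Generator, n_alleles: int = 2
) -> np.ndarray:
    """Random (V, G) base assignments with ≥2 distinct bases per position.

    Every position is a true variant: the strains are split between
    ``n_alleles`` distinct bases, each allele carried by at least one
    strain.
    """
    if G < 2:
        raise ValueError("variant positions need at least two strains")
    tau = np.zeros((V, G), dtype=np.int8)
    for v in range(V):
        bases = rng.choice(4, size=n_alleles, replace=False)
        assign = rng.integers(0, n_alleles, size=G)
        while np.unique(assign).size < 2:
            assign = rng.integers(0, n_alleles, size=G)
        tau[v] = bases[assign]
    return tau


def dirichlet_frequencies(G: int, S: int, rng: np.random.Generator, a: float = 1.0) -> np.ndarray:
    """Per-sample strain proportions π (G, S) ~ symmetric Dirichlet(a)."""
    return rng.dirichlet(np.full(G, a), size=S).T


def simulate_variant_tensor(
    tau: np.ndarray,
    pi: np.ndarray,
    eps: np.ndarray,
    mean_depth: float | np.ndarray,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Draw a (V, S, 4) count tensor from the model's forward process.

    Depth at each (v, s) is Poisson with the given mean (scalar, per-sample
    vector, or full (V, S) array); counts are multinomial over
    Σ_g Σ_b τ_{v,g,b} π_{g,s} ε_{b,a}.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tau = np.asarray(tau)
    pi = np.asarray(pi, dtype=float)
    eps = np.asarray(eps, dtype=float)
    V, G = tau.shape
    S = pi.shape[1]
    probs = np.einsum("gs,vga->vsa", pi, eps[tau])
    probs /= probs.sum(axis=2, keepdims=True)
    depth = rng.poisson(np.broadcast_to(np.asarray(mean_depth, dtype=float), (V, S)))
    return rng.multinomial(depth, probs)


# ---------------------------------------------------------------------------
# gene data


@dataclass
class GeneTruth:
    eta: np.ndarray  # (F, G) binary presence
    tau_gene: np.ndarray  # (F, L, G) base indices
    n_variants: np.ndarray  # (F,) true variant positions per gene (rest padded)


def simulate_gene_truth(
    F: int,
    G: int,
    rng: np.random.Generator,
    presence_prob: float = 0.7,
    n_variant_positions: int = 20,
) -> GeneTruth:
    """Random binary η and per-gene haplotype bases.

    Genes carried by ≥2 strains get ``n_variant_positions`` variant
    positions at which the carriers are split between two bases; genes with
    fewer carriers have no variant positions (a single-copy gene can show
    no within-gene mixture).
    """
    eta = (rng.random((F, G)) < presence_prob).astype(np.int8)
    tau = np.zeros((F, n_variant_positions, G), dtype=np.int8)
    n_var = np.zeros(F, dtype=int)
    for f in range(F):
        carriers = np.flatnonzero(eta[f])
        if len(carriers) >= 2:
            n_var[f] = n_variant_positions
            for l in range(n_variant_positions):
                b0, b1 = rng.choice(4, size=2, replace=False)
                split = rng.integers(1, len(carriers))
                order = rng.permutation(carriers)
                tau[f, l, :] = b0
                tau[f, l, order[:split]] = b1
    return GeneTruth(eta, tau, n_var)


def simulate_gene_data(
    truth: GeneTruth,
    gamma: np.ndarray,
    pi: np.ndarray,
    eps: np.ndarray,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Coverage matrix and gene variant tensor from the gene forward model.

    x_{f,s} ~ Poisson(λ_{f,s}) with λ = Σ_g η γ (reported as reals);
    variant counts at each retained position are multinomial over the
    carrier-renormalised mixture, with depth Poisson(λ_{f,s}).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eta = truth.eta.astype(float)
    F, L, G = truth.tau_gene.shape
    S = gamma.shape[1]
    lam = eta @ gamma  # (F, S)
    x = rng.poisson(lam).astype(float)

    m = np.zeros((F, L, S, 4), dtype=np.int64)
    carrier_pi = eta[:, :, None] * pi[None, :, :]  # (F, G, S)
    denom = carrier_pi.sum(axis=1)  # (F, S)
    for f in range(F):
        if truth.n_variants[f] == 0 or denom[f].max() == 0:
            continue
        pi_f = carrier_pi[f] / np.maximum(denom[f], 1e-300)[None, :]  # (G, S)
        probs = np.einsum("gs,lga->lsa", pi_f, eps[truth.tau_gene[f]])
        probs /= probs.sum(axis=2, keepdims=True)
        depth = rng.poisson(np.broadcast_to(lam[f], (truth.n_variants[f], S)))
        m[f, : truth.n_variants[f]] = rng.multinomial(depth, probs[: truth.n_variants[f]])
    return x, m


# ---------------------------------------------------------------------------
# presets


def strain_mock_design(
    G: int = 5,
    S: int = 64,
    genome_length: float = 5.0e6,
    seed: int = 0,
) -> CommunityDesign:
    """Single target species with G strains across S samples."""
    return CommunityDesign(
        strains_per_species=[G],
        genome_lengths=[genome_length] * G,
        n_samples=S,
        seed=seed,
    )


@dataclass
class VariantDetectionTruth:
    counts: np.ndarray  # (n_positions, 4) aggregated over samples
    is_variant: np.ndarray  # (n_positions,) bool
    eps: np.ndarray
    pi: np.ndarray


def simulate_variant_detection_dataset(
    n_invariant: int = 50_000,
    n_variant: int = 6_000,
    G: int = 5,
    S: int = 64,
    mean_depth_per_sample: float = 8.0,
    eps_diag: float = 0.995,
    min_minor_fraction: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> VariantDetectionTruth:
    """Aggregated base counts with known variant labels.

    Variant positions split the strains between two bases and are retained
    only if the expected aggregate minor-base fraction is at least
    ``min_minor_fraction``; invariant positions carry one base in every
    strain. Counts are drawn per sample under the shared error matrix and
    aggregated, matching what the variant caller consumes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = seed_error_matrix(eps_diag)
    pi = dirichlet_frequencies(G, S, rng)

    tau_var = np.empty((n_variant, G), dtype=np.int8)
    got = 0
    mean_pi = pi.mean(axis=1)  # equal expected depth per sample
    while got < n_variant:
        cand = random_haplotypes(min(4 * (n_variant - got), 20000), G, rng)
        for row in cand:
            fractions = np.bincount(row, weights=mean_pi, minlength=4)
            minor = np.sort(fractions)[-2]
            if minor >= min_minor_fraction:
                tau_var[got] = row
                got += 1
                if got == n_variant:
                    break

    base_inv = rng.integers(0, 4, size=n_invariant).astype(np.int8)
    tau_inv = np.repeat(base_inv[:, None], G, axis=1)
    tau = np.concatenate([tau_var, tau_inv], axis=0)
    is_variant = np.zeros(n_variant + n_invariant, dtype=bool)
    is_variant[:n_variant] = True

    V = tau.shape[0]
    agg = np.zeros((V, 4), dtype=np.int64)
    # per-sample draws aggregated on the fly to bound memory
    for s in range(S):
        probs = np.einsum("g,vga->va", pi[:, s], eps[tau])
        probs /= probs.sum(axis=1, keepdims=True)
        depth = rng.poisson(mean_depth_per_sample, size=V)
        agg += rng.multinomial(depth, probs)
    perm = rng.permutation(V)
    return VariantDetectionTruth(agg[perm], is_variant[perm], eps, pi)
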