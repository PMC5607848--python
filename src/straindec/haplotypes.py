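"""Deconvolution of variant tensors into strain haplotypes.

The observable is a V×S×4 tensor of base counts at V variant positions in
S samples. The model assumes G underlying strains, each with a one-hot
base assignment τ_{v,g,·} at every position, per-sample relative
frequencies π_{·,s} on the simplex, and a shared row-stochastic error
matrix ε, so that counts at (v,s) are multinomial with base probabilities

    P(a | v, s) = Σ_g Σ_b τ_{v,g,b} π_{g,s} ε_{b,a}.

Inference is by Gibbs sampling with conjugate updates: τ positions are
conditionally independent given (π, ε) and are sampled from their 4-state
conditionals strain by strain; ε and π are sampled via two auxiliary
allocation variables — ν (observed base a attributed to true base b) and
ξ (ν further attributed to strain g) — whose multinomial conditionals make
the Dirichlet priors (symmetric α on π columns, δ on ε rows) conjugate.

The sampler is initialised from a non-negative tensor factorisation of the
per-position base proportions (multiplicative Kullback–Leibler updates on
the stacked 4V×S matrix), which places the chain near a high-posterior
region. Model size G is chosen by scanning G, comparing posterior mean
deviance drops across replicates, and counting haplotypes that are both
reproducible across replicates (low SNV uncertainty) and non-negligibly
abundant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .variants import seed_error_matrix, validate_error_matrix

MIN_VARIANTS_FOR_DECONVOLUTION = 5


# ---------------------------------------------------------------------------
# likelihood


def log_likelihood(
    n: np.ndarray, tau: np.ndarray, pi: np.ndarray, eps: np.ndarray
) -> float:
    """Log-likelihood of the count tensor, multinomial coefficients included.

    ``tau`` is an integer (V, G) array of base indices.
    """
    n = np.asarray(n, dtype=float)
    mix = mixture_probabilities(tau, pi, eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        core = np.where(n > 0, n * np.log(mix), 0.0).sum()
    totals = n.sum(axis=2)
    coeff = gammaln(totals + 1.0).sum() - gammaln(n + 1.0).sum()
    return float(core + coeff)


def mixture_probabilities(tau: np.ndarray, pi: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """P(a | v, s) = Σ_g π_{g,s} ε_{τ_{v,g}, a}, shape (V, S, 4)."""
    E = eps[tau]  # (V, G, 4)
    return np.einsum("gs,vga->vsa", pi, E)


def deviance(n: np.ndarray, tau: np.ndarray, pi: np.ndarray, eps: np.ndarray) -> float:
    return -2.0 * log_likelihood(n, tau, pi, eps)


# ---------------------------------------------------------------------------
# NTF initialisation


@dataclass
class NTFResult:
    tau_soft: np.ndarray  # (V, G, 4), rows over bases sum to 1
    pi: np.ndarray  # (G, S), columns sum to 1
    dkl_trace: list[float]

    @property
    def tau(self) -> np.ndarray:
        """Discretised (V, G) base indices (per-position argmax)."""
        return np.argmax(self.tau_soft, axis=2)


def generalised_kl(p: np.ndarray, p_hat: np.ndarray) -> float:
    """Σ p log(p/p̂) + p̂ − p with the 0·log0 = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(p / p_hat), 0.0)
    return float((term + p_hat - p).sum())


def ntf_initialize(
    n: np.ndarray,
    G: int,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-5,
    max_iter: int = 5000,
) -> NTFResult:
    """Rank-G factorisation of per-position base proportions.

    The proportions p_{v,s,a} = n_{v,s,a}/n_{v,s,·} are stacked into a
    4V×S matrix and factorised as τ′·π by multiplicative updates minimising
    the generalised Kullback–Leibler divergence, with τ′ renormalised over
    bases per (position, strain) and π per sample each iteration. Stops
    when the divergence reduction falls below ``tol``.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = np.asarray(n, dtype=float)
    V, S, _ = n.shape
    totals = n.sum(axis=2)
    if np.any(totals.sum(axis=1) == 0):
        raise ValueError("positions with zero counts in every sample must be excluded")
    with np.errstate(invalid="ignore"):
        p = np.where(totals[:, :, None] > 0, n / np.maximum(totals, 1)[:, :, None], 0.0)
    P = p.transpose(2, 0, 1).reshape(4 * V, S)  # w = v + a·V

    tau = rng.uniform(0.1, 1.0, size=(4 * V, G))
    tau /= tau.reshape(4, V, G).sum(axis=0).reshape(1, V, G).repeat(4, axis=0).reshape(4 * V, G)
    pi = rng.uniform(0.1, 1.0, size=(G, S))
    pi /= pi.sum(axis=0, keepdims=True)

    tiny = 1e-12
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        approx = tau @ pi
        R = P / np.maximum(approx, tiny)
        tau *= (R @ pi.T) / np.maximum(pi.sum(axis=1), tiny)
        approx = tau @ pi
        R = P / np.maximum(approx, tiny)
        pi *= (tau.T @ R) / np.maximum(tau.sum(axis=0), tiny)[:, None]
        # normalisation: τ′ over bases per (v, g); π over strains per sample
        block = tau.reshape(4, V, G)
        block /= np.maximum(block.sum(axis=0, keepdims=True), tiny)
        tau = block.reshape(4 * V, G)
        pi /= np.maximum(pi.sum(axis=0, keepdims=True), tiny)
        d = generalised_kl(P, np.maximum(tau @ pi, tiny))
        trace.append(d)
        if prev - d < tol:
            break
        prev = d

    tau_soft = tau.reshape(4, V, G).transpose(1, 2, 0)  # (V, G, 4)
    return NTFResult(tau_soft, pi, trace)


# ---------------------------------------------------------------------------
# Gibbs sampler


@dataclass
class GibbsChain:
    """Stored posterior samples and their summaries."""

    tau_samples: np.ndarray  # (T, V, G) int8 base indices
    pi_samples: np.ndarray  # (T, G, S)
    eps_samples: np.ndarray  # (T, 4, 4)
    log_likelihoods: np.ndarray  # (T,)
    log_posteriors: np.ndarray  # (T,)

    @property
    def n_samples(self) -> int:
        return self.tau_samples.shape[0]

    @property
    def pi_mean(self) -> np.ndarray:
        return self.pi_samples.mean(axis=0)

    @property
    def eps_mean(self) -> np.ndarray:
        return self.eps_samples.mean(axis=0)

    @property
    def tau_mean(self) -> np.ndarray:
        """Posterior mean one-hot τ, shape (V, G, 4)."""
        T, V, G = self.tau_samples.shape
        mean = np.zeros((V, G, 4))
        for t in range(T):
            onehot = np.eye(4)[self.tau_samples[t]]
            mean += onehot
        return mean / T

    @property
    def tau_map(self) -> np.ndarray:
        """Discretised posterior-mean τ (argmax, lowest-index tie-break)."""
        return np.argmax(self.tau_mean, axis=2)

    @property
    def max_posterior_sample(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = int(np.argmax(self.log_posteriors))
        return self.tau_samples[i], self.pi_samples[i], self.eps_samples[i]

    def posterior_mean_deviance(self, n: np.ndarray) -> float:
        devs = [
            deviance(n, self.tau_samples[t], self.pi_samples[t], self.eps_samples[t])
            for t in range(self.n_samples)
        ]
        return float(np.mean(devs))


def posterior_mean_deviance(chain: GibbsChain, n: np.ndarray) -> float:
    """Mean over stored samples of −2 log-likelihood (coefficients included)."""
    return chain.posterior_mean_deviance(n)


class GibbsSampler:
    """One-chain Gibbs sampler over (τ, π, ε) for a variant tensor.

    Exposes :meth:`step` so invariants of the auxiliary allocations can be
    inspected; :func:`gibbs_run` is the high-level driver.
    """

    def __init__(
        self,
        n: np.ndarray,
        G: int,
        tau_init: np.ndarray,
        pi_init: np.ndarray,
        alpha: float = 1.0,
        delta: float = 0.1,
        eps_init: np.ndarray | None = None,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        self.n = np.asarray(n)
        if self.n.ndim != 3 or self.n.shape[2] != 4:
            raise ValueError("variant tensor must have shape (V, S, 4)")
        self.V, self.S, _ = self.n.shape
        self.G = G
        self.alpha = alpha
        self.delta = delta
        self.rng = (
            rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        )
        self.tau = np.asarray(tau_init, dtype=np.int8).copy()
        if self.tau.shape != (self.V, G):
            raise ValueError("tau_init must have shape (V, G) of base indices")
        self.pi = np.asarray(pi_init, dtype=float).copy()
        if self.pi.shape != (G, self.S):
            raise ValueError("pi_init must have shape (G, S)")
        self.pi /= self.pi.sum(axis=0, keepdims=True)
        self.eps = seed_error_matrix() if eps_init is None else validate_error_matrix(eps_init)
        self.nu: np.ndarray | None = None  # last sampled (V, S, 4, 4) a×b
        self.xi: np.ndarray | None = None  # last sampled (V, S, 4, G) b×g (a summed out)

    # -- τ ------------------------------------------------------------
    def _sample_tau(self) -> None:
        E = self.eps[self.tau]  # (V, G, 4)
        weighted = self.pi[None, :, :, None] * E[:, :, None, :]  # (V, G, S, 4)
        total = weighted.sum(axis=1)  # (V, S, 4)
        for g in range(self.G):
            rest = total - weighted[:, g]  # (V, S, 4)
            # candidate log-likelihoods for the 4 bases of strain g
            cand = rest[:, None] + self.pi[g][None, None, :, None] * self.eps[None, :, None, :]
            with np.errstate(divide="ignore"):
                ll = np.einsum("vsa,vbsa->vb", self.n, np.log(np.maximum(cand, 1e-300)))
            ll -= ll.max(axis=1, keepdims=True)
            w = np.exp(ll)
            w /= w.sum(axis=1, keepdims=True)
            u = self.rng.random(self.V)
            new = (np.cumsum(w, axis=1) < u[:, None]).sum(axis=1).astype(np.int8)
            self.tau[:, g] = new
            weighted[:, g] = self.pi[g][None, :, None] * self.eps[new][:, None, :]
            total = rest + weighted[:, g]

    # -- ν and ε -------------------------------------------------------
    def _sample_nu_eps(self) -> None:
        onehot = np.eye(4)[self.tau]  # (V, G, 4) over true base b
        w = np.einsum("gs,vgb->vsb", self.pi, onehot)  # (V, S, 4) weight of true base b
        zeta = w[:, :, None, :] * self.eps.T[None, None, :, :]  # (V, S, a, b)
        zeta /= np.maximum(zeta.sum(axis=3, keepdims=True), 1e-300)
        self.nu = self.rng.multinomial(self.n, zeta)  # (V, S, 4a, 4b)
        counts_ab = self.nu.sum(axis=(0, 1))  # (a, b): observed a from true b
        for b in range(4):
            self.eps[b] = self.rng.dirichlet(counts_ab[:, b] + self.delta)

    # -- ξ and π -------------------------------------------------------
    def _sample_xi_pi(self) -> None:
        assert self.nu is not None
        nu_b = self.nu.sum(axis=2)  # (V, S, b): reads attributed to true base b
        onehot = np.eye(4)[self.tau]  # (V, G, 4)
        # ψ weights over g for fixed (v, s, b): ∝ τ_{v,g,b} π_{g,s} (ε cancels)
        psi = onehot.transpose(0, 2, 1)[:, None, :, :] * self.pi.T[None, :, None, :]
        norm = psi.sum(axis=3, keepdims=True)
        uniform = np.full_like(psi, 1.0 / self.G)
        psi = np.where(norm > 0, psi / np.maximum(norm, 1e-300), uniform)
        self.xi = self.rng.multinomial(nu_b, psi)  # (V, S, 4b, G)
        counts_sg = self.xi.sum(axis=(0, 2))  # (S, G)
        for s in range(self.S):
            self.pi[:, s] = self.rng.dirichlet(counts_sg[s] + self.alpha)

    def step(self) -> None:
        """One full Gibbs iteration: τ sweep, (ν, ε), (ξ, π)."""
        self._sample_tau()
        self._sample_nu_eps()
        self._sample_xi_pi()

    def log_posterior(self) -> float:
        ll = log_likelihood(self.n, self.tau, self.pi, self.eps)
        lp = (self.alpha - 1.0) * np.log(np.maximum(self.pi, 1e-300)).sum()
        le = (self.delta - 1.0) * np.log(np.maximum(self.eps, 1e-300)).sum()
        lt = -self.V * self.G * np.log(4.0)
        return float(ll + lp + le + lt)


def gibbs_run(
    n: np.ndarray,
    G: int,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    burn: int = 100,
    samples: int = 100,
    alpha: float = 1.0,
    delta: float = 0.1,
    seed: int | np.random.Generator = 0,
    eps_init: np.ndarray | None = None,
) -> GibbsChain:
    """NTF-initialised (unless ``init`` given) Gibbs run; returns the chain.

    ``init`` is a (τ, π) pair with τ as (V, G) base indices. A single seed
    governs both the NTF initialisation and the sampler.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if init is None:
        ntf = ntf_initialize(n, G, seed=rng)
        init = (ntf.tau, ntf.pi)
    tau0, pi0 = init
    sampler = GibbsSampler(n, G, tau0, pi0, alpha=alpha, delta=delta, eps_init=eps_init, rng=rng)
    for _ in range(burn):
        sampler.step()
    V, S = sampler.V, sampler.S
    tau_s = np.empty((samples, V, G), dtype=np.int8)
    pi_s = np.empty((samples, G, S))
    eps_s = np.empty((samples, 4, 4))
    lls = np.empty(samples)
    lps = np.empty(samples)
    for t in range(samples):
        sampler.step()
        tau_s[t] = sampler.tau
        pi_s[t] = sampler.pi
        eps_s[t] = sampler.eps
        lls[t] = log_likelihood(n, sampler.tau, sampler.pi, sampler.eps)
        lps[t] = sampler.log_posterior()
    return GibbsChain(tau_s, pi_s, eps_s, lls, lps)


def _ntf_tau_given_pi(
    n: np.ndarray, pi: np.ndarray, rng: np.random.Generator, max_iter: int = 300, tol: float = 1e-6
) -> np.ndarray:
    """Per-position base assignments consistent with a *fixed* π.

    Runs only the τ′ multiplicative update of the stacked-proportion NTF
    with π held at the supplied values, so the resulting haplotype labels
    match π's strain labels; returns the discretised (V, G) argmax. The
    objective decomposes over positions, making this a cheap, good starting
    point for τ-only Gibbs passes (a consensus start tends to lock the
    high-depth conditionals into a wrong mode).
    """
    n = np.asarray(n, dtype=float)
    V, S, _ = n.shape
    G = pi.shape[0]
    totals = n.sum(axis=2)
    with np.errstate(invalid="ignore"):
        p = np.where(totals[:, :, None] > 0, n / np.maximum(totals, 1)[:, :, None], 0.0)
    P = p.transpose(2, 0, 1).reshape(4 * V, S)
    tau = rng.uniform(0.1, 1.0, size=(4 * V, G))
    tiny = 1e-12
    pi_row_sum = np.maximum(pi.sum(axis=1), tiny)
    prev = np.inf
    for _ in range(max_iter):
        R = P / np.maximum(tau @ pi, tiny)
        tau *= (R @ pi.T) / pi_row_sum
        block = tau.reshape(4, V, G)
        block /= np.maximum(block.sum(axis=0, keepdims=True), tiny)
        tau = block.reshape(4 * V, G)
        d = generalised_kl(P, np.maximum(tau @ pi, tiny))
        if prev - d < tol:
            break
        prev = d
    return np.argmax(tau.reshape(4, V, G), axis=0).astype(np.int8)


def assign_all_positions(
    full_tensor: np.ndarray,
    chain: GibbsChain,
    burn: int = 100,
    samples: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Assign haplotype bases at *every* variant position.

    π and ε need only a subset of positions to be estimated accurately, so
    the main run can use a random subset; this pass then iterates τ-only
    Gibbs updates through the stored (π_t, ε_t) samples over the full
    tensor and returns the discretised posterior-mean τ, shape (V, G).
    τ starts from a fixed-π NTF fit so its labels agree with the chain's.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = np.asarray(full_tensor)
    V, S, _ = n.shape
    G = chain.pi_samples.shape[1]
    T = chain.n_samples
    tau = _ntf_tau_given_pi(n, chain.pi_mean, rng)
    sampler = GibbsSampler(n, G, tau, chain.pi_samples[0], rng=rng)
    mean = np.zeros((V, G, 4))
    kept = 0
    for it in range(burn + samples):
        idx = it % T
        sampler.pi = chain.pi_samples[idx].copy()
        sampler.eps = chain.eps_samples[idx].copy()
        sampler._sample_tau()
        if it >= burn:
            mean += np.eye(4)[sampler.tau]
            kept += 1
    mean /= kept
    return np.argmax(mean, axis=2)


# ---------------------------------------------------------------------------
# replicate comparison and model selection


def match_haplotypes(tau_a: np.ndarray, tau_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one pairing of haplotypes by Hamming fraction.

    Returns (permutation applied to columns of ``tau_b``, per-pair Hamming
    fractions). Handles unequal strain counts by matching min(Ga, Gb) pairs.
    """
    V, Ga = tau_a.shape
    Gb = tau_b.shape[1]
    dist = np.empty((Ga, Gb))
    for i in range(Ga):
        dist[i] = (tau_a[:, i][:, None] != tau_b).mean(axis=0)
    rows, cols = linear_sum_assignment(dist)
    return cols, dist[rows, cols]


def snv_uncertainty(run: np.ndarray, replicates: list[np.ndarray]) -> np.ndarray:
    """Mean SNV uncertainty of each haplotype in ``run``.

    For each haplotype, per replicate, the Hamming fraction to its closest
    match (non-exclusive nearest neighbour) is found; the mean over
    replicates is returned, shape (G,). Label permutations have no effect.
    """
    run = np.asarray(run)
    if not replicates:
        return np.zeros(run.shape[1])
    fracs = []
    for rep in replicates:
        rep = np.asarray(rep)
        if rep.shape[0] != run.shape[0]:
            raise ValueError("replicate runs must cover the same variant positions")
        d = np.empty((run.shape[1], rep.shape[1]))
        for i in range(run.shape[1]):
            d[i] = (run[:, i][:, None] != rep).mean(axis=0)
        fracs.append(d.min(axis=1))
    return np.mean(fracs, axis=0)


def select_haplotype_number(
    deviances: dict[int, list[float]],
    uncertainties: dict[int, np.ndarray] | None = None,
    abundances: dict[int, np.ndarray] | None = None,
    d: float = 0.05,
    u_max: float = 0.10,
    a_min: float = 0.05,
) -> int:
    """Automated choice of the number of haplotypes G.

    The upper limit G_U is the largest G before the relative drop in mean
    posterior deviance first falls below ``d`` (G_U = G − 1 at the first
    small drop; G_max if every drop is large). Among G ≤ G_U the returned
    value maximises the number of haplotypes with mean SNV uncertainty
    below ``u_max`` and mean relative abundance above ``a_min`` (smallest G
    on ties). With a single G supplied, that G is returned.
    """
    gs = sorted(deviances)
    if len(gs) == 1:
        return gs[0]
    means = {g: float(np.mean(deviances[g])) for g in gs}
    G_U = gs[-1]
    for prev, cur in zip(gs, gs[1:]):
        drop = (means[prev] - means[cur]) / means[prev] if means[prev] > 0 else 0.0
        if drop < d:
            G_U = prev
            break
    best_g, best_count = gs[0], -1
    for g in gs:
        if g > G_U:
            break
        unc = np.asarray(uncertainties.get(g, np.zeros(g))) if uncertainties else np.zeros(g)
        ab = np.asarray(abundances.get(g, np.full(g, 1.0 / g))) if abundances else np.full(g, 1.0 / g)
        count = int(((unc < u_max) & (ab > a_min)).sum())
        if count > best_count:
            best_g, best_count = g, count
    return best_g
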