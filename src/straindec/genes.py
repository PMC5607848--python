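"""Inference of the accessory genome: which strain carries which gene.

With the strain frequencies π̂ and error matrix ε̂ fixed from the core-gene
run, each gene f is scored by two likelihoods assumed separable:

* a coverage likelihood — each strain contributes reads independently, so
  the observed mean coverage x_{f,s} is Poisson with mean
  λ_{f,s} = Σ_g η_{f,g} γ_{g,s}, where γ_{g,s} = π_{g,s} Y_s is the strain
  coverage and Y_s the mean total core coverage in sample s (the Γ(x+1)
  term handles continuous coverages);
* a variant likelihood — base counts at the gene's variant positions are
  multinomial under the strains actually carrying the gene, with π̂
  renormalised to that carrier set.

Copy numbers are binary (η ∈ {0,1}). A Gibbs sweep jointly samples, for
each gene and strain in turn, the presence indicator together with the
strain's bases at the gene's variant positions: τ is marginalised
analytically (positions are conditionally independent, uniform prior) to
give the η conditional, then sampled from its per-position conditional
when the gene is present. The sampler is initialised from a one-sided
multiplicative NMF update of the coverage model alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import BaseCountTable

_LAMBDA_FLOOR = np.finfo(float).eps
_LOGP_FLOOR = np.log(1e-16)  # per-read penalty when no carrier can explain reads


# ---------------------------------------------------------------------------
# strain coverage


def total_core_coverage(core_counts: BaseCountTable, core_lengths: dict[str, int]) -> np.ndarray:
    """Y_s: total bases on core genes per sample over total core length."""
    total_length = sum(core_lengths.values())
    if total_length <= 0:
        raise ValueError("total core-gene length must be positive")
    return core_counts.counts.sum(axis=(0, 2)) / total_length


def strain_coverage(pi: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """γ_{g,s} = π_{g,s} Y_s; columns conserve Σ_g γ = Y."""
    pi = np.asarray(pi, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise ValueError("per-sample core coverages must be non-negative")
    return pi * Y[None, :]


# ---------------------------------------------------------------------------
# coverage-only NMF initialisation


def coverage_loglik(eta_row: np.ndarray, x_row: np.ndarray, gamma: np.ndarray) -> float:
    """Poisson log-likelihood of one gene's coverages given a carrier set."""
    lam = np.maximum(eta_row @ gamma, _LAMBDA_FLOOR)
    return float((-lam + x_row * np.log(lam) - gammaln(x_row + 1.0)).sum())


def eta_nmf_init(
    x: np.ndarray, gamma: np.ndarray, tol: float = 1e-5, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous and rounded binary η from the coverage model alone.

    Iterates the single multiplicative update
    η ← η · [Σ_s γ x/(η·γ)] / [Σ_s γ] (the KL-NMF update with γ fixed)
    until the generalised KL divergence changes by less than ``tol``, then
    rounds to the nearest integer and clips to {0, 1}.
    """
    x = np.asarray(x, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma.sum(axis=1) == 0):
        raise ValueError("every strain needs nonzero total coverage")
    F, S = x.shape
    G = gamma.shape[0]
    eta = np.full((F, G), 0.5)
    denom = gamma.sum(axis=1)  # (G,)
    prev = np.inf
    for _ in range(max_iter):
        lam = np.maximum(eta @ gamma, _LAMBDA_FLOOR)
        R = x / lam
        eta *= (R @ gamma.T) / denom
        lam = np.maximum(eta @ gamma, _LAMBDA_FLOOR)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(x > 0, x * np.log(x / lam), 0.0)
        d = float((term + lam - x).sum())
        if abs(prev - d) < tol:
            break
        prev = d
    rounded = np.clip(np.rint(eta), 0, 1).astype(np.int8)
    return eta, rounded


# ---------------------------------------------------------------------------
# joint η / τ Gibbs sampler


@dataclass
class GeneAssignment:
    eta_mean: np.ndarray  # (F, G) posterior presence probability
    eta_call: np.ndarray  # (F, G) binary call (mean rounded at 0.5)
    tau_call: np.ndarray  # (F, L, G) base index, −1 where strain absent


def eta_gibbs(
    m: np.ndarray,
    x: np.ndarray,
    pi: np.ndarray,
    eps: np.ndarray,
    gamma: np.ndarray,
    eta_init: np.ndarray | None = None,
    burn: int = 20,
    samples: int = 20,
    eta_prior: float = 1.0,
    tau_warmup: int = 10,
    seed: int | np.random.Generator = 0,
) -> GeneAssignment:
    """Sample gene presence/absence and non-core haplotype bases.

    Parameters
    ----------
    m
        Gene variant tensor, shape (F, L, S, 4). Genes with fewer than L
        variant positions are padded with all-zero counts (zero-count
        positions contribute nothing to the multinomial likelihood).
    x
        Mean gene coverages, shape (F, S).
    pi, eps
        Strain frequencies (G, S) and error matrix, held fixed (typically
        posterior means from the core-gene run).
    gamma
        Strain coverages γ_{g,s}, shape (G, S).
    eta_prior
        Presence odds P(η=1)/P(η=0) of the (binary-truncated) geometric
        prior; 1.0 is flat.
    tau_warmup
        Number of initial sweeps in which η stays frozen at its
        initialisation and only τ is resampled. The τ state starts at the
        aggregate consensus, which misrepresents minority-base carriers;
        letting τ equilibrate first keeps the high-depth η conditionals
        from locking onto a wrong mode.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = np.asarray(m)
    x = np.asarray(x, dtype=float)
    pi = np.asarray(pi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    F, L, S, _ = m.shape
    G = pi.shape[0]
    log_prior_present = np.log(eta_prior)

    if eta_init is None:
        _, eta = eta_nmf_init(x, gamma)
        eta = eta.astype(np.int8)
    else:
        eta = np.asarray(eta_init, dtype=np.int8).copy()

    # τ init: aggregate consensus per gene position (all strains)
    agg = m.sum(axis=2)  # (F, L, 4)
    consensus = np.argmax(agg, axis=2).astype(np.int8)  # (F, L)
    tau = np.repeat(consensus[:, :, None], G, axis=2)  # (F, L, G)

    eta_sum = np.zeros((F, G))
    tau_sum = np.zeros((F, L, G, 4))
    kept = 0
    mf = m.astype(float)
    total_reads = mf.sum(axis=(1, 2, 3))

    for it in range(tau_warmup + burn + samples):
        freeze_eta = it < tau_warmup
        for g in range(G):
            other = eta.astype(float)
            other[:, g] = 0.0
            # mixture over the other carriers, unnormalised by Σπ
            w_other = other @ pi  # (F, S)
            onehot = np.eye(4, dtype=float)[tau]  # (F, L, G, 4) over base b
            carrier = other[:, None, :, None] * onehot  # mask strains
            mix_other = np.einsum("flgb,gs,ba->flsa", carrier, pi, eps)
            # η = 0: probabilities renormalised over the other carriers
            denom0 = np.maximum(w_other, 1e-300)[:, None, :, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                logp0 = np.log(np.maximum(mix_other / denom0, 1e-300))
            ll_v0 = np.einsum("flsa,flsa->f", mf, logp0)
            no_carrier = w_other.sum(axis=1) == 0
            ll_v0[no_carrier] = total_reads[no_carrier] * _LOGP_FLOOR
            lam0 = np.maximum(other @ gamma, _LAMBDA_FLOOR)
            ll_x0 = (-lam0 + x * np.log(lam0)).sum(axis=1)
            # η = 1: per-position log-lik for each candidate base of strain g
            denom1 = (w_other + pi[g][None, :])[:, None, :, None]
            ll1b = np.empty((F, L, 4))
            for b in range(4):
                mix1 = (mix_other + pi[g][None, None, :, None] * eps[b][None, None, None, :]) / denom1
                ll1b[:, :, b] = np.einsum("flsa,flsa->fl", mf, np.log(np.maximum(mix1, 1e-300)))
            ll_v1 = (logsumexp(ll1b, axis=2) - np.log(4.0)).sum(axis=1)
            lam1 = np.maximum((other @ gamma) + gamma[g][None, :], _LAMBDA_FLOOR)
            ll_x1 = (-lam1 + x * np.log(lam1)).sum(axis=1)

            score1 = ll_v1 + ll_x1 + log_prior_present
            score0 = ll_v0 + ll_x0
            if freeze_eta:
                present = eta[:, g] == 1
            else:
                p1 = 1.0 / (1.0 + np.exp(np.clip(score0 - score1, -700, 700)))
                present = rng.random(F) < p1
                eta[:, g] = present.astype(np.int8)
            # sample τ for present strains from the per-position conditional
            llb = ll1b - ll1b.max(axis=2, keepdims=True)
            wb = np.exp(llb)
            wb /= wb.sum(axis=2, keepdims=True)
            u = rng.random((F, L))
            draw = (np.cumsum(wb, axis=2) < u[:, :, None]).sum(axis=2).astype(np.int8)
            tau[:, :, g] = np.where(present[:, None], draw, tau[:, :, g])
        if it >= tau_warmup + burn:
            eta_sum += eta
            tau_sum += np.eye(4)[tau] * eta[:, None, :, None]
            kept += 1

    eta_mean = eta_sum / kept
    eta_call = (eta_mean >= 0.5).astype(np.int8)
    tau_call = np.where(
        (eta_call[:, None, :] == 1) & (tau_sum.sum(axis=3) > 0),
        np.argmax(tau_sum, axis=3),
        -1,
    ).astype(np.int8)
    return GeneAssignment(eta_mean, eta_call, tau_call)
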