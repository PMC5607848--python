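"""Likelihood-ratio detection of single-nucleotide variants.

Each candidate position is summarised by the total count of each base
across all samples, t_a. Under the null, all reads derive from one true
base (the consensus, m0 = argmax_a t_a) observed through a 4×4
position-independent error matrix ε; under the alternative, a second base
m1 is present at relative consensus frequency p:

    log H0 = Σ_a t_a log ε_{m0,a}
    log H1(p) = Σ_a t_a log(p ε_{m0,a} + (1 − p) ε_{m1,a}),

with p maximised over [0.5, 1 − p_min]. The statistic −2 log(H0/H1) is
referred to a χ²(1) upper tail (the multinomial coefficient cancels in the
ratio). ε itself is estimated by iterating: classify positions with a BH
false-discovery-rate cut, re-estimate ε from base transitions at
non-variant positions, repeat until the variant set is stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

DEFAULT_P_MIN = 0.01
DEFAULT_FDR = 1e-3

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def seed_error_matrix(diag: float = 0.99) -> np.ndarray:
    """Rough starting ε: ``diag`` on the diagonal, remainder split evenly."""
    eps = np.full((4, 4), (1.0 - diag) / 3.0)
    np.fill_diagonal(eps, diag)
    return eps


def validate_error_matrix(eps: np.ndarray) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    if eps.shape != (4, 4):
        raise ValueError("error matrix must be 4x4")
    if not np.allclose(eps.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("error matrix rows must sum to 1")
    if np.any(eps <= 0):
        raise ValueError("error matrix entries must be positive")
    off = eps.copy()
    np.fill_diagonal(off, -np.inf)
    if np.any(np.diag(eps) <= off.max(axis=1)):
        raise ValueError("error matrix diagonal must dominate its row")
    return eps


def consensus_bases(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Consensus m0 and secondary m1 base indices for aggregated counts.

    Ties are broken toward the lowest base index (A<C<G<T), which is
    ``np.argmax``'s behaviour.
    """
    t = np.atleast_2d(np.asarray(t))
    m0 = np.argmax(t, axis=1)
    masked = t.copy().astype(float)
    masked[np.arange(len(t)), m0] = -np.inf
    m1 = np.argmax(masked, axis=1)
    return m0, m1


def _h1_loglik(t: np.ndarray, e0: np.ndarray, e1: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Σ_a t_a log(p ε_{m0,a} + (1−p) ε_{m1,a}) for per-position p."""
    mix = p[:, None] * e0 + (1.0 - p[:, None]) * e1
    return np.einsum("ia,ia->i", t, np.log(mix))


def _optimise_consensus_freq(
    t: np.ndarray, e0: np.ndarray, e1: np.ndarray, p_min: float, tol: float = 1e-6
) -> np.ndarray:
    """Maximise the two-base log-likelihood over p ∈ [0.5, 1−p_min].

    The objective is concave in p (log of an affine function), so a
    vectorised golden-section search converges to the stated tolerance.
    """
    lo = np.full(len(t), 0.5)
    hi = np.full(len(t), 1.0 - p_min)
    c = hi - _GOLDEN * (hi - lo)
    d = lo + _GOLDEN * (hi - lo)
    fc = _h1_loglik(t, e0, e1, c)
    fd = _h1_loglik(t, e0, e1, d)
    while np.max(hi - lo) > tol:
        take_left = fc > fd
        hi = np.where(take_left, d, hi)
        lo = np.where(take_left, lo, c)
        c = hi - _GOLDEN * (hi - lo)
        d = lo + _GOLDEN * (hi - lo)
        fc = _h1_loglik(t, e0, e1, c)
        fd = _h1_loglik(t, e0, e1, d)
    return 0.5 * (lo + hi)


def lr_test(
    t: np.ndarray,
    eps: np.ndarray,
    p_min: float = DEFAULT_P_MIN,
    fast: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Likelihood-ratio statistic, χ²(1) p-value and consensus frequency p̂.

    Parameters
    ----------
    t
        Aggregated counts, shape (n, 4) (a single position may be passed as
        shape (4,)).
    eps
        Row-stochastic 4×4 error matrix.
    p_min
        Minimum observable variant frequency; the consensus frequency is
        searched over [0.5, 1 − p_min]. Must lie in (0, 0.5).
    fast
        If True, skip the one-dimensional optimisation and plug in
        p̂ = t_{m0}/T (clipped to the search interval) — the screening mode
        used for large gene sets.
    """
    eps = validate_error_matrix(eps)
    if not 0 < p_min < 0.5:
        raise ValueError("p_min must be in (0, 0.5)")
    t = np.atleast_2d(np.asarray(t, dtype=float))
    T = t.sum(axis=1)
    if np.any(T <= 0):
        raise ValueError("positions with zero total count must be excluded before testing")
    m0, m1 = consensus_bases(t)
    e0 = eps[m0]
    e1 = eps[m1]
    ll0 = np.einsum("ia,ia->i", t, np.log(e0))
    if fast:
        p_hat = np.clip(t[np.arange(len(t)), m0] / T, 0.5, 1.0 - p_min)
    else:
        p_hat = _optimise_consensus_freq(t, e0, e1, p_min)
    ll1 = _h1_loglik(t, e0, e1, p_hat)
    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    pval = chi2.sf(stat, df=1)
    pval = np.where(stat == 0.0, 1.0, pval)
    return stat, pval, p_hat


def bh_fdr(p_values: np.ndarray, cutoff: float = DEFAULT_FDR) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values and the rejected set (q < cutoff)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < cutoff


@dataclass
class VariantCallResult:
    """Per-position calls plus the fitted error matrix."""

    table: pd.DataFrame  # columns: m0, m1, p_hat, stat, p_value, q_value, is_variant
    error_matrix: np.ndarray
    n_iterations: int
    converged: bool

    @property
    def is_variant(self) -> np.ndarray:
        return self.table["is_variant"].to_numpy()


def _transition_matrix(t: np.ndarray, m0: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Row-normalised base-transition counts (true = consensus, observed = column).

    A base never observed as consensus gives no transition data; its row
    falls back to the seed values rather than a flat pseudocount-only row
    (which would violate diagonal dominance).
    """
    trans = np.full((4, 4), pseudocount)
    fallback = seed_error_matrix()
    out = np.empty((4, 4))
    for a in range(4):
        sel = m0 == a
        if sel.any():
            trans[a] += t[sel].sum(axis=0)
            out[a] = trans[a] / trans[a].sum()
        else:
            out[a] = fallback[a]
    return out


def fit_error_matrix(
    t: np.ndarray,
    p_min: float = DEFAULT_P_MIN,
    fdr: float = DEFAULT_FDR,
    max_iter: int = 20,
    fast: bool = False,
    eps_init: np.ndarray | None = None,
) -> VariantCallResult:
    """Iteratively estimate ε and classify variant positions.

    Starting from a rough ε, positions are classified by the LR test with a
    BH cut at ``fdr``; ε is then re-estimated as the observed base-transition
    frequency across non-variant positions (with a pseudocount of 1 per cell
    to keep entries positive) and the loop repeats until the variant set and
    ε stop changing, or ``max_iter`` is reached.
    """
    t = np.atleast_2d(np.asarray(t, dtype=float))
    T = t.sum(axis=1)
    if np.any(T <= 0):
        warnings.warn(f"excluding {int((T <= 0).sum())} positions with zero depth")
    usable = T > 0
    tu = t[usable]
    if len(tu) == 0:
        raise ValueError("no positions with positive depth")
    eps = seed_error_matrix() if eps_init is None else validate_error_matrix(eps_init)

    prev_variants: np.ndarray | None = None
    converged = False
    for iteration in range(1, max_iter + 1):
        stat, pval, p_hat = lr_test(tu, eps, p_min=p_min, fast=fast)
        qval, variants = bh_fdr(pval, cutoff=fdr)
        if not (~variants).any():
            raise ValueError("every position was called a variant; cannot estimate the error matrix")
        m0, m1 = consensus_bases(tu)
        new_eps = _transition_matrix(tu[~variants], m0[~variants])
        if (
            prev_variants is not None
            and np.array_equal(variants, prev_variants)
            and np.allclose(new_eps, eps, atol=1e-10)
        ):
            converged = True
            break
        prev_variants = variants
        eps = new_eps
    else:
        iteration = max_iter
    if not converged and max_iter > 1:
        # final classification under the last ε
        stat, pval, p_hat = lr_test(tu, eps, p_min=p_min, fast=fast)
        qval, variants = bh_fdr(pval, cutoff=fdr)
        m0, m1 = consensus_bases(tu)
        if prev_variants is not None and np.array_equal(variants, prev_variants):
            converged = True
        else:
            warnings.warn(f"error-matrix refinement did not converge in {max_iter} iterations")

    table = pd.DataFrame(
        {
            "m0": -1,
            "m1": -1,
            "p_hat": np.nan,
            "stat": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
            "is_variant": False,
        },
        index=range(len(t)),
    )
    idx = np.flatnonzero(usable)
    table.loc[idx, "m0"] = m0
    table.loc[idx, "m1"] = m1
    table.loc[idx, "p_hat"] = p_hat
    table.loc[idx, "stat"] = stat
    table.loc[idx, "p_value"] = pval
    table.loc[idx, "q_value"] = qval
    table.loc[idx, "is_variant"] = variants
    table["is_variant"] = table["is_variant"].astype(bool)
    return VariantCallResult(table, eps, iteration, converged)


def call_variants_fast(
    t: np.ndarray,
    eps: np.ndarray,
    fdr: float = DEFAULT_FDR,
    p_min: float = DEFAULT_P_MIN,
) -> pd.DataFrame:
    """One-pass screening of a large position set with a fixed ε.

    Identical to the LR pipeline but with p̂ estimated as the consensus
    ratio t_{m0}/T instead of optimised; positions with zero depth are
    skipped (marked non-variant with NaN statistics).
    """
    t = np.atleast_2d(np.asarray(t, dtype=float))
    usable = t.sum(axis=1) > 0
    table = pd.DataFrame(
        {
            "m0": -1,
            "m1": -1,
            "p_hat": np.nan,
            "stat": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
            "is_variant": False,
        },
        index=range(len(t)),
    )
    if usable.any():
        tu = t[usable]
        stat, pval, p_hat = lr_test(tu, eps, p_min=p_min, fast=True)
        qval, variants = bh_fdr(pval, cutoff=fdr)
        m0, m1 = consensus_bases(tu)
        idx = np.flatnonzero(usable)
        table.loc[idx, "m0"] = m0
        table.loc[idx, "m1"] = m1
        table.loc[idx, "p_hat"] = p_hat
        table.loc[idx, "stat"] = stat
        table.loc[idx, "p_value"] = pval
        table.loc[idx, "q_value"] = qval
        table.loc[idx, "is_variant"] = variants
    table["is_variant"] = table["is_variant"].astype(bool)
    return table
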