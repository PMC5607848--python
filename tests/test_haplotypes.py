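import itertools

import numpy as np
import pytest

from straindec import (
    GibbsSampler,
    assign_all_positions,
    gibbs_run,
    log_likelihood,
    match_haplotypes,
    ntf_initialize,
    seed_error_matrix,
    select_haplotype_number,
    snv_uncertainty,
)
from straindec import simulate as sim
from straindec.haplotypes import deviance, generalised_kl


class TestNTF:
    def test_noiseless_recovery_up_to_permutation(self):
        rng = np.random.default_rng(2)
        G, V, S = 2, 20, 10
        pi = sim.dirichlet_frequencies(G, S, rng)
        tau = sim.random_haplotypes(V, G, rng)
        # noiseless proportions scaled to large integer counts
        onehot = np.eye(4)[tau]  # (V, G, 4)
        p = np.einsum("gs,vga->vsa", pi, onehot)
        n = np.round(p * 100000).astype(int)
        res = ntf_initialize(n, G, seed=5)
        assert res.dkl_trace[-1] < 1e-4
        perm, ham = match_haplotypes(tau, res.tau)
        assert ham.max() == 0.0

    def test_rank_one_fit_matches_analytic_minimum(self):
        rng = np.random.default_rng(3)
        n = rng.integers(0, 40, size=(15, 6, 4))
        n[:, :, 0] += 1  # no all-zero (v, s) cells
        res = ntf_initialize(n, 1, seed=1)
        np.testing.assert_allclose(res.pi, 1.0)
        # with pi fixed at 1 the optimal tau row is the mean of proportions
        p = n / n.sum(axis=2, keepdims=True)
        tau_star = p.mean(axis=1)  # (V, 4)
        P = p.transpose(2, 0, 1).reshape(-1, 6)
        best = generalised_kl(P, np.maximum(tau_star.T.reshape(-1, 1), 1e-12))
        assert res.dkl_trace[-1] == pytest.approx(best, rel=1e-3, abs=1e-6)

    def test_dkl_non_increasing(self):
        rng = np.random.default_rng(4)
        n = rng.integers(0, 30, size=(25, 8, 4))
        n[:, :, 1] += 1
        res = ntf_initialize(n, 3, seed=2)
        trace = np.array(res.dkl_trace)
        assert np.all(np.diff(trace) <= 1e-8)

    def test_all_zero_position_rejected(self):
        n = np.zeros((3, 2, 4), dtype=int)
        n[0, 0, 0] = 5
        with pytest.raises(ValueError):
            ntf_initialize(n, 2, seed=0)


class TestGibbs:
    def test_single_strain_degenerates_to_consensus(self):
        rng = np.random.default_rng(5)
        tau = sim.random_haplotypes(30, 2, rng)[:, :1]
        pi = np.ones((1, 8))
        n = sim.simulate_variant_tensor(tau, pi, seed_error_matrix(0.995), 60, rng)
        chain = gibbs_run(n, 1, burn=30, samples=30, seed=3)
        consensus = np.argmax(n.sum(axis=1), axis=1)
        assert (chain.tau_map[:, 0] == consensus).mean() == 1.0
        np.testing.assert_allclose(chain.pi_mean, 1.0)

    def test_recovers_truth_on_forward_simulation(self, small_recovery_sim):
        d = small_recovery_sim
        chain = gibbs_run(d["tensor"], d["G"], burn=100, samples=100, seed=1)
        perm, ham = match_haplotypes(d["tau"], chain.tau_map)
        assert (1 - ham.mean()) >= 0.99
        rmse = np.sqrt(((d["pi"] - chain.pi_mean[perm]) ** 2).mean())
        assert rmse < 0.05

    def test_map_sample_beats_initialisation(self, small_recovery_sim):
        d = small_recovery_sim
        ntf = ntf_initialize(d["tensor"], d["G"], seed=1)
        init_ll = log_likelihood(
            d["tensor"], ntf.tau, ntf.pi, seed_error_matrix()
        )
        chain = gibbs_run(
            d["tensor"], d["G"], init=(ntf.tau, ntf.pi), burn=100, samples=100, seed=1
        )
        tau_star, pi_star, eps_star = chain.max_posterior_sample
        assert log_likelihood(d["tensor"], tau_star, pi_star, eps_star) >= init_ll

    def test_auxiliary_allocations_conserved_each_sweep(self):
        rng = np.random.default_rng(6)
        G, S, V = 3, 5, 12
        pi = sim.dirichlet_frequencies(G, S, rng)
        tau = sim.random_haplotypes(V, G, rng)
        n = sim.simulate_variant_tensor(tau, pi, seed_error_matrix(0.99), 30, rng)
        sampler = GibbsSampler(n, G, tau, pi, rng=7)
        for _ in range(5):
            sampler.step()
            # ν sums over true bases b to the observed counts
            np.testing.assert_array_equal(sampler.nu.sum(axis=3), n)
            # ξ splits ν (a summed out) over strains
            np.testing.assert_array_equal(
                sampler.xi.sum(axis=3), sampler.nu.sum(axis=2)
            )
            np.testing.assert_allclose(sampler.pi.sum(axis=0), 1.0)
            np.testing.assert_allclose(sampler.eps.sum(axis=1), 1.0)

    def test_posterior_matches_exhaustive_enumeration(self):
        """τ-only Gibbs vs full enumeration on a V=2, S=2, G=2 instance.

        The instance uses a soft error matrix so that single-site
        conditionals are not near-deterministic; with a sharp ε the two
        symmetric modes of the τ posterior exchange too rarely for any
        finite chain to equilibrate (a mixing property, not a correctness
        one — the conditionals themselves are exact).
        """
        eps = seed_error_matrix(0.7)
        pi = np.array([[0.7, 0.4], [0.3, 0.6]])
        n = np.array(
            [[[2, 1, 0, 0], [1, 2, 0, 0]], [[0, 2, 1, 0], [0, 1, 2, 0]]]
        )
        logps = {}
        for cfg in itertools.product(range(4), repeat=4):
            tau = np.array(cfg).reshape(2, 2)
            logps[cfg] = log_likelihood(n, tau, pi, eps)
        keys = list(logps)
        lp = np.array([logps[k] for k in keys])
        post = np.exp(lp - lp.max())
        post /= post.sum()

        sampler = GibbsSampler(
            n, 2, np.zeros((2, 2), dtype=np.int8), pi, eps_init=eps,
            rng=np.random.default_rng(7),
        )
        counts: dict = {}
        n_samples, burn = 50_000, 1000
        for it in range(burn + n_samples):
            sampler._sample_tau()
            if it >= burn:
                k = tuple(sampler.tau.flatten().tolist())
                counts[k] = counts.get(k, 0) + 1
        emp = np.array([counts.get(k, 0) / n_samples for k in keys])
        tv = 0.5 * np.abs(emp - post).sum()
        assert tv <= 0.05

    def test_parameter_recovery_at_high_depth(self):
        rng = np.random.default_rng(8)
        G, S, V = 2, 10, 40
        pi = sim.dirichlet_frequencies(G, S, rng)
        tau = sim.random_haplotypes(V, G, rng)
        n = sim.simulate_variant_tensor(tau, pi, seed_error_matrix(0.995), 1000, rng)
        chain = gibbs_run(n, G, burn=50, samples=50, seed=2)
        _, ham = match_haplotypes(tau, chain.tau_map)
        assert ham.max() == 0.0


class TestDeviance:
    def test_direct_evaluation(self):
        # one position, one sample, counts (3,1,0,0), single haplotype A:
        # L = 0.97^3 * 0.01 * C(4,1) -> deviance ≈ 6.62
        n = np.array([[[3, 1, 0, 0]]])
        eps = np.array(
            [
                [0.97, 0.01, 0.01, 0.01],
                [0.01, 0.97, 0.01, 0.01],
                [0.01, 0.01, 0.97, 0.01],
                [0.01, 0.01, 0.01, 0.97],
            ]
        )
        d = deviance(n, np.array([[0]]), np.ones((1, 1)), eps)
        expected = -2 * np.log(0.97**3 * 0.01 * 4)
        assert d == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(6.62, abs=0.01)

    def test_perfect_fit_limit(self):
        n = np.array([[[50, 0, 0, 0]]])
        eps = np.full((4, 4), 1e-12)
        np.fill_diagonal(eps, 1 - 3e-12)
        d = deviance(n, np.array([[0]]), np.ones((1, 1)), eps)
        assert 0 <= d < 1e-8

    def test_non_negative_on_random_parameters(self, rng):
        for _ in range(20):
            G, S, V = 2, 3, 4
            pi = sim.dirichlet_frequencies(G, S, rng)
            tau = rng.integers(0, 4, size=(V, G))
            n = rng.integers(0, 15, size=(V, S, 4))
            assert deviance(n, tau, pi, seed_error_matrix(0.99)) >= 0


class TestAssignAllPositions:
    def test_held_out_positions_recovered(self, small_recovery_sim):
        d = small_recovery_sim
        subset = np.arange(0, 100, 2)
        chain = gibbs_run(d["tensor"][subset], d["G"], burn=60, samples=60, seed=4)
        tau_full = assign_all_positions(d["tensor"], chain, burn=50, samples=50, seed=5)
        assert tau_full.shape == (100, d["G"])
        perm, ham = match_haplotypes(d["tau"], tau_full)
        assert (1 - ham.mean()) >= 0.99

    def test_monomorphic_position_gets_consensus_everywhere(self):
        rng = np.random.default_rng(9)
        G, S = 2, 6
        pi = sim.dirichlet_frequencies(G, S, rng)
        tau = sim.random_haplotypes(20, G, rng)
        n = sim.simulate_variant_tensor(tau, pi, seed_error_matrix(0.995), 50, rng)
        full = np.concatenate([n, np.zeros((1, S, 4), dtype=int)])
        full[-1, :, 0] = 40  # only base A observed in all samples
        chain = gibbs_run(n, G, burn=40, samples=40, seed=1)
        tau_full = assign_all_positions(full, chain, burn=30, samples=30, seed=2)
        assert (tau_full[-1] == 0).all()


class TestReplicateUncertainty:
    def test_label_permutation_gives_zero(self, rng):
        run = rng.integers(0, 4, size=(60, 3))
        rep = run[:, [2, 0, 1]]
        np.testing.assert_allclose(snv_uncertainty(run, [rep]), 0.0)

    def test_direct_fraction(self, rng):
        run = rng.integers(0, 2, size=(100, 1))
        rep = run.copy()
        rep[:10, 0] = 3 - run[:10, 0]  # differs at exactly 10 of 100 positions
        assert snv_uncertainty(run, [rep])[0] == pytest.approx(0.10)

    def test_identical_single_replicate(self, rng):
        run = rng.integers(0, 4, size=(40, 2))
        np.testing.assert_allclose(snv_uncertainty(run, [run.copy()]), 0.0)

    def test_mismatched_length_rejected(self, rng):
        with pytest.raises(ValueError):
            snv_uncertainty(
                rng.integers(0, 4, size=(10, 2)), [rng.integers(0, 4, size=(9, 2))]
            )


class TestModelSelection:
    def test_hand_worked_deviance_sequence(self):
        # drops: 1000->400 (60%), 400->390 (2.5% < 5%) so G_U = 2
        deviances = {1: [1000.0], 2: [400.0], 3: [390.0]}
        unc = {1: np.zeros(1), 2: np.zeros(2), 3: np.zeros(3)}
        ab = {1: np.ones(1), 2: np.full(2, 0.5), 3: np.full(3, 1 / 3)}
        assert select_haplotype_number(deviances, unc, ab, d=0.05) == 2

    def test_large_drops_throughout_allow_g_max(self):
        deviances = {1: [1000.0], 2: [500.0], 3: [250.0]}
        assert select_haplotype_number(deviances) == 3

    def test_single_g_returned(self):
        assert select_haplotype_number({1: [123.0]}) == 1

    def test_unreliable_haplotypes_reduce_choice(self):
        deviances = {1: [1000.0], 2: [400.0], 3: [200.0]}
        unc = {1: np.zeros(1), 2: np.zeros(2), 3: np.array([0.0, 0.3, 0.4])}
        ab = {1: np.ones(1), 2: np.full(2, 0.5), 3: np.full(3, 1 / 3)}
        # at G=3 only one haplotype is reproducible; G=2 offers two
        assert select_haplotype_number(deviances, unc, ab) == 2
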