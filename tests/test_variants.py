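import numpy as np
import pytest

from straindec import (
    bh_fdr,
    call_variants_fast,
    consensus_bases,
    fit_error_matrix,
    lr_test,
    seed_error_matrix,
)
from straindec.variants import validate_error_matrix


def grid_lr_statistic(t, eps, p_min, step=1e-4):
    """Independent oracle: evaluate the two-base likelihood on a dense grid."""
    t = np.asarray(t, dtype=float)
    order = np.argsort(t)[::-1]
    m0, m1 = order[0], order[1]
    if t[m0] == t[m1]:  # replicate the lowest-index tie-break
        tied = np.flatnonzero(t == t.max())
        m0 = tied[0]
        rest = [a for a in range(4) if a != m0]
        m1 = rest[int(np.argmax(t[rest]))]
    ll0 = (t * np.log(eps[m0])).sum()
    grid = np.arange(0.5, 1.0 - p_min + step / 2, step)
    lls = [
        (t * np.log(p * eps[m0] + (1 - p) * eps[m1])).sum() for p in grid
    ]
    return max(0.0, 2.0 * (max(lls) - ll0))


EPS = seed_error_matrix(0.997)


class TestConsensus:
    @pytest.mark.parametrize(
        "counts,m0,m1",
        [
            ((10, 0, 0, 0), 0, 1),  # tie among zeros broken by base order
            ((0, 5, 7, 0), 2, 1),
            ((5, 5, 0, 0), 0, 1),  # tie at the top: lowest index wins
        ],
    )
    def test_examples(self, counts, m0, m1):
        got0, got1 = consensus_bases(np.array([counts]))
        assert (got0[0], got1[0]) == (m0, m1)


class TestLRTest:
    def test_pure_consensus_gives_zero_statistic(self):
        stat, pval, _ = lr_test(np.array([100, 0, 0, 0]), EPS)
        assert stat[0] == 0.0
        assert pval[0] == 1.0
        assert stat[0] == pytest.approx(grid_lr_statistic([100, 0, 0, 0], EPS, 0.01))

    def test_balanced_counts_highly_significant(self):
        stat, pval, p_hat = lr_test(np.array([50, 50, 0, 0]), EPS)
        assert stat[0] > 10
        assert pval[0] < 1e-4
        oracle = grid_lr_statistic([50, 50, 0, 0], EPS, 0.01)
        assert stat[0] == pytest.approx(oracle, rel=1e-4)

    def test_single_read_cannot_support_two_bases(self):
        stat, pval, _ = lr_test(np.array([1, 0, 0, 0]), EPS)
        assert stat[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_optimised_statistic_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 200, size=(20, 4))
        t = t[t.sum(axis=1) > 0]
        stat, _, _ = lr_test(t, EPS)
        for row, s in zip(t, stat):
            assert s == pytest.approx(grid_lr_statistic(row, EPS, 0.01), abs=1e-3)

    def test_statistic_monotone_in_minor_count(self):
        T = 100
        stats = []
        for k in range(0, T // 2 + 1, 5):
            s, _, _ = lr_test(np.array([T - k, k, 0, 0]), EPS)
            stats.append(s[0])
        assert all(b >= a - 1e-9 for a, b in zip(stats, stats[1:]))

    def test_sample_permutation_invariance(self, rng):
        # only sample-aggregated counts enter the test
        tensor = rng.integers(0, 20, size=(10, 6, 4))
        agg1 = tensor.sum(axis=1)
        agg2 = tensor[:, rng.permutation(6)].sum(axis=1)
        s1, _, _ = lr_test(agg1, EPS)
        s2, _, _ = lr_test(agg2, EPS)
        np.testing.assert_allclose(s1, s2)

    def test_invalid_error_matrix_rejected(self):
        bad = np.full((4, 4), 0.25) + np.eye(4) * 0.1  # rows do not sum to 1
        with pytest.raises(ValueError):
            lr_test(np.array([5, 5, 0, 0]), bad)
        with pytest.raises(ValueError):
            validate_error_matrix(np.full((4, 4), 0.25))  # no diagonal dominance


class TestFastMode:
    def test_ratio_estimate_close_to_optimised(self):
        stat_opt, _, _ = lr_test(np.array([50, 50, 0, 0]), EPS)
        table = call_variants_fast(np.array([[50, 50, 0, 0]]), EPS)
        assert table["p_hat"][0] == pytest.approx(0.5)
        assert table["stat"][0] == pytest.approx(stat_opt[0], rel=0.05)

    def test_pure_consensus_clipped(self):
        table = call_variants_fast(np.array([[100, 0, 0, 0]]), EPS, p_min=0.01)
        assert table["p_hat"][0] == pytest.approx(0.99)
        assert table["stat"][0] == 0.0

    def test_zero_depth_skipped(self):
        table = call_variants_fast(np.array([[0, 0, 0, 0], [9, 1, 0, 0]]), EPS)
        assert not table["is_variant"][0]
        assert np.isnan(table["stat"][0])
        assert np.isfinite(table["stat"][1])


class TestBH:
    def test_hand_worked_step_up(self):
        # sorted p: 1e-4 (q=4e-4), 0.02 (q=0.04), 0.03 (q=0.04), 0.9 (q=0.9)
        q, rej = bh_fdr(np.array([0.0001, 0.02, 0.03, 0.9]), cutoff=0.05)
        assert rej.sum() == 3
        np.testing.assert_allclose(q, [4e-4, 0.04, 0.04, 0.9])

    def test_all_ones_no_rejections(self):
        _, rej = bh_fdr(np.ones(10), cutoff=0.05)
        assert rej.sum() == 0

    def test_single_p_identity(self):
        q, _ = bh_fdr(np.array([0.001]), cutoff=0.05)
        assert q[0] == pytest.approx(0.001)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            q, rej = bh_fdr(p, cutoff=0.05)
            ref_rej, ref_q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(q, ref_q)
            # statsmodels rejects at q <= alpha; agreement checked through q
            np.testing.assert_array_equal(q < 0.05, rej)


class TestErrorMatrixFit:
    def test_noise_free_single_haplotype(self):
        # 200 error-free positions, 50 per consensus base
        t = np.zeros((200, 4), dtype=int)
        for a in range(4):
            t[a * 50 : (a + 1) * 50, a] = 100
        res = fit_error_matrix(t)
        assert res.is_variant.sum() == 0
        assert np.all(np.diag(res.error_matrix) >= 0.999)

    def test_recovers_known_error_rates_and_variants(self):
        # 1e5 positions, 1% true variants at a 50/50 mixture, known ε
        rng = np.random.default_rng(3)
        eps_true = seed_error_matrix(0.995)
        n_pos, frac_var = 100_000, 0.01
        n_var = int(n_pos * frac_var)
        true_base = rng.integers(0, 4, size=n_pos)
        probs = eps_true[true_base]
        alt = (true_base[:n_var] + rng.integers(1, 4, size=n_var)) % 4
        probs[:n_var] = 0.5 * eps_true[true_base[:n_var]] + 0.5 * eps_true[alt]
        depth = rng.poisson(100, size=n_pos)
        t = rng.multinomial(depth, probs)
        keep = depth > 0
        res = fit_error_matrix(t[keep])
        truth = np.zeros(n_pos, dtype=bool)
        truth[:n_var] = True
        truth = truth[keep]
        recall = (res.is_variant & truth).sum() / truth.sum()
        assert recall >= 0.97
        off = ~np.eye(4, dtype=bool)
        rel_err = np.abs(res.error_matrix[off] - eps_true[off]) / eps_true[off]
        assert np.all(rel_err < 0.20)

    def test_refit_is_fixed_point(self):
        rng = np.random.default_rng(4)
        t = rng.multinomial(rng.poisson(80, 5000), seed_error_matrix(0.99)[rng.integers(0, 4, 5000)])
        first = fit_error_matrix(t[t.sum(axis=1) > 0])
        again = fit_error_matrix(
            t[t.sum(axis=1) > 0], eps_init=first.error_matrix
        )
        np.testing.assert_allclose(again.error_matrix, first.error_matrix, atol=1e-8)
        np.testing.assert_array_equal(again.is_variant, first.is_variant)

    def test_type_one_error_within_chi2_slack(self):
        # single haplotype + known ε: P(p < 0.05) under H0 should be <= 0.075
        rng = np.random.default_rng(9)
        eps_true = seed_error_matrix(0.995)
        base = rng.integers(0, 4, size=20_000)
        t = rng.multinomial(rng.poisson(200, 20_000), eps_true[base])
        t = t[t.sum(axis=1) > 0]
        _, pval, _ = lr_test(t, eps_true)
        assert (pval < 0.05).mean() <= 0.075
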