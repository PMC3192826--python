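"""Covariance, TSE complexity, hierarchy, node removal and bootstrap tests."""

import numpy as np
import pytest
from scipy.linalg import solve_continuous_lyapunov

from vbgen import (
    bootstrap_mean_diff,
    node_removal_scan,
    stationary_covariance,
    tns_and_hierarchy,
    tse_complexity,
)
from vbgen.workbench import fixture_generator


def _random_stable(rng, n, margin=1.0):
    A = rng.standard_normal((n, n))
    return A - (np.linalg.eigvals(A).real.max() + margin) * np.eye(n)


class TestStationaryCovariance:
    def test_isotropic_decay(self):
        C = stationary_covariance(-2.0 * np.eye(4), sigma=1.0)
        np.testing.assert_allclose(C, np.eye(4) / 4.0, atol=1e-12)

    def test_matches_direct_lyapunov_solve(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            W = _random_stable(rng, n)
            sigma = float(rng.uniform(0.5, 2))
            C = stationary_covariance(W, sigma)
            C_ref = solve_continuous_lyapunov(W, -sigma**2 * np.eye(n))
            assert np.abs(C - C_ref).max() < 1e-7

    def test_result_symmetric_psd(self, rng):
        C = stationary_covariance(_random_stable(rng, 6), 1.0)
        np.testing.assert_allclose(C, C.T, atol=1e-10)
        assert np.linalg.eigvalsh(C).min() > -1e-10

    def test_near_defective_matrix_falls_back_to_lyapunov(self):
        W = np.array([[-1.0, 1.0], [0.0, -1.0 - 1e-14]])
        with pytest.warns(RuntimeWarning, match="ill-conditioned"):
            C = stationary_covariance(W, 1.0, cond_threshold=1e4)
        C_ref = solve_continuous_lyapunov(W, -np.eye(2))
        np.testing.assert_allclose(C, C_ref, atol=1e-10)

    def test_unstable_matrix_rejected(self):
        with pytest.raises(ValueError, match="stable"):
            stationary_covariance(np.array([[1.0]]))

    def test_diagonal_matches_simulation_sd(self, normal_matrices):
        from vbgen import simulate

        cm = normal_matrices[0]
        C = stationary_covariance(cm.W, 1.0)
        panel = simulate(cm.W, sigma=1.0, dt=1e-3, duration=120.0, seed=2)
        sd_sim = panel.data.std(axis=1)
        sd_ana = np.sqrt(np.diag(C))
        assert np.abs(sd_sim / sd_ana - 1).max() < 0.25
        assert np.corrcoef(sd_sim, sd_ana)[0, 1] > 0.99


class TestTSEComplexity:
    def test_independent_channels_have_zero_complexity(self):
        assert tse_complexity(np.eye(9)) == pytest.approx(0.0, abs=1e-9)
        assert tse_complexity(np.diag([1.0, 2.0, 5.0, 0.3])) == pytest.approx(0.0, abs=1e-9)

    def test_monte_carlo_agrees_with_enumeration(self, rng):
        W = _random_stable(rng, 8)
        C = stationary_covariance(W, 1.0)
        exact = tse_complexity(C, mode="exact")
        mc, se = tse_complexity(C, mode="mc", n_subset_samples=400, seed=1, with_stderr=True)
        assert abs(mc - exact) < 3 * se + 1e-12
        assert exact >= -1e-10

    def test_permutation_and_scale_invariance(self, rng):
        C = stationary_covariance(_random_stable(rng, 7), 1.0)
        base = tse_complexity(C, mode="exact")
        perm = rng.permutation(7)
        assert tse_complexity(C[np.ix_(perm, perm)], mode="exact") == pytest.approx(base)
        assert tse_complexity(3.7 * C, mode="exact") == pytest.approx(base)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            tse_complexity(np.diag([1.0, 0.0]))

    def test_background_group_least_complex(self, normal_matrices, background_matrices):
        tse_n = [
            tse_complexity(stationary_covariance(cm.W, 1.0)) for cm in normal_matrices
        ]
        tse_b = [
            tse_complexity(stationary_covariance(cm.W, 1.0)) for cm in background_matrices
        ]
        assert np.mean(tse_n) > np.mean(tse_b)
        assert max(tse_b) < min(tse_n)


class TestHierarchy:
    def test_uniform_network_flat_curve(self):
        n = 10
        W = np.ones((n, n)) - 3 * np.eye(n)
        table, hier = tns_and_hierarchy(W, C=np.eye(n))
        np.testing.assert_allclose(hier.normalized_tns, 1.0)
        assert hier.half_rank == n // 2

    def test_star_network_hub_ranks_first(self):
        W = fixture_generator("star")
        table, hier = tns_and_hierarchy(W, C=np.eye(W.shape[0]))
        assert table.loc[0, "rank"] == 1
        assert hier.half_rank == 1
        assert hier.normalized_tns[0] == 1.0

    def test_tns_invariant_under_sign_flips(self, rng):
        W = _random_stable(rng, 6)
        flips = rng.choice([-1.0, 1.0], size=W.shape)
        t1, _ = tns_and_hierarchy(W, C=np.eye(6))
        t2, _ = tns_and_hierarchy(W * flips, C=np.eye(6))
        np.testing.assert_allclose(t1["tns"], t2["tns"])

    def test_curve_non_increasing_and_rank_is_permutation(self, rng):
        W = _random_stable(rng, 8)
        table, hier = tns_and_hierarchy(W, C=np.eye(8))
        assert np.all(np.diff(hier.normalized_tns) <= 1e-12)
        assert sorted(table["rank"]) == list(range(1, 9))

    def test_normal_hierarchy_steeper_than_background(
        self, normal_matrices, background_matrices
    ):
        def half_rank(cm):
            _, h = tns_and_hierarchy(cm.W, C=np.eye(cm.n_nodes))
            return h.half_rank

        hn = [half_rank(cm) for cm in normal_matrices]
        hb = [half_rank(cm) for cm in background_matrices]
        assert np.mean(hn) < np.mean(hb)

    def test_excitation_inhibition_balance(self, normal_matrices, entrained_matrix):
        """Reconstructed peaked-group matrices balance excitation against
        inhibition: across a batch, excitatory and inhibitory input totals
        correlate positively and net input correlates negatively with net
        output (directional sign test over n >= 5 matrices)."""
        ei, io = [], []
        for cm in [*normal_matrices, entrained_matrix]:
            table, _ = tns_and_hierarchy(cm.W, C=np.eye(cm.n_nodes))
            ei.append(
                np.corrcoef(table["excitatory_input"], table["inhibitory_input"])[0, 1]
            )
            io.append(np.corrcoef(table["net_input"], table["net_output"])[0, 1])
        assert np.mean(ei) > 0 and sum(v > 0 for v in ei) > len(ei) / 2
        assert np.mean(io) < 0 and sum(v < 0 for v in io) > len(io) / 2


class TestNodeRemoval:
    def test_isotropic_network_removal_changes_nothing(self):
        scan = node_removal_scan(-2.0 * np.eye(5), 1.0, np.geomspace(0.5, 10, 16))
        np.testing.assert_allclose(scan.errors, 0.0, atol=1e-12)

    def test_twin_nodes_have_equal_errors(self):
        # nodes 0 and 1 are exchangeable by symmetry
        W = np.array(
            [
                [-2.0, 0.5, 1.0],
                [0.5, -2.0, 1.0],
                [0.3, 0.3, -3.0],
            ]
        )
        scan = node_removal_scan(W, 1.0, np.geomspace(0.5, 10, 32))
        assert scan.errors[0] == pytest.approx(scan.errors[1], rel=1e-9)

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError):
            node_removal_scan(-np.eye(2))

    def test_hub_removal_dominates_in_rhythmic_networks(
        self, normal_matrices, background_matrices
    ):
        grid = np.geomspace(0.3, 30, 64)
        corr_n = [node_removal_scan(cm.W, 1.0, grid).corr_rank for cm in normal_matrices]
        corr_b = [node_removal_scan(cm.W, 1.0, grid).corr_rank for cm in background_matrices]
        assert np.mean(corr_n) < 0  # strong nodes (low rank) matter most
        assert np.mean(np.abs(corr_n)) > np.mean(np.abs(corr_b))


class TestBootstrap:
    def test_identical_groups_zero_difference(self):
        res = bootstrap_mean_diff([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_iter=2000, seed=0)
        assert res.observed == 0.0
        assert 0 <= res.p_value <= 1

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(100):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            pvals.append(
                bootstrap_mean_diff(a, b, n_iter=1000, seed=1, alternative="left").p_value
            )
        pvals = np.asarray(pvals)
        # left-tail p of a true null is ~Uniform(0, 1)
        assert 0.35 < pvals.mean() < 0.65
        assert 0.02 <= np.mean(pvals <= 0.1) <= 0.25

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(7)
        b = rng.standard_normal(20)
        a = b - 5.0 * b.std()
        res = bootstrap_mean_diff(a, b, n_iter=100_000, seed=2, alternative="left")
        assert res.p_value < 0.01

    def test_small_iteration_count_warns(self):
        with pytest.warns(RuntimeWarning, match="n_iter"):
            bootstrap_mean_diff([1.0, 2.0], [3.0, 4.0], n_iter=100, seed=0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_diff([], [1.0], n_iter=2000)
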