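"""MSM estimation: counting, reversible MLE, timescales, tICA."""

import numpy as np
import pytest
from scipy.optimize import minimize

from ecsampler.errors import (CardinalityError, ConnectivityError, LagError,
                              MatrixError)
from ecsampler.kmc import kmc_ensemble
from ecsampler.msm import (CountMatrix, DiscreteTrajectory, TransitionMatrix,
                           cluster_kmeans, count_and_trim, estimate_reversible,
                           implied_timescales, implied_timescales_from_matrix,
                           propagate, stationary_distribution, tica_project)


class TestClusterKMeans:
    def test_separated_blobs(self, rng):
        x = np.concatenate([rng.normal(0, 0.05, 50),
                            rng.normal(10, 0.05, 50)])[:, None]
        (dtraj,), _ = cluster_kmeans([x], k=2, seed=0)
        labels = dtraj.states
        assert len(set(labels[:50])) == 1
        assert len(set(labels[50:])) == 1
        assert labels[0] != labels[-1]

    def test_deterministic(self, rng):
        x = rng.normal(size=(200, 3))
        (a,), _ = cluster_kmeans([x], k=5, seed=42)
        (b,), _ = cluster_kmeans([x], k=5, seed=42)
        assert np.array_equal(a.states, b.states)

    def test_k_equals_points_zero_variance(self):
        x = np.array([[0.0], [1.0], [5.0]])
        (d,), centers = cluster_kmeans([x], k=3, seed=0)
        assert sorted(centers.ravel()) == pytest.approx([0.0, 1.0, 5.0])

    def test_too_many_clusters(self):
        with pytest.raises(CardinalityError):
            cluster_kmeans([np.zeros((3, 1))], k=5, seed=0)


class TestCountAndTrim:
    def test_hand_enumeration(self):
        C, active = count_and_trim([DiscreteTrajectory([0, 0, 1, 1, 0])], 1)
        assert np.array_equal(C.counts, [[1, 1], [1, 1]])
        assert np.array_equal(active, [0, 1])
        assert C.counts.sum() == 4  # len - lag sliding windows

    def test_absorbing_state_trimmed(self):
        C, active = count_and_trim([DiscreteTrajectory([0, 1, 0, 1, 2])], 1)
        assert 2 not in active

    def test_lag_too_long(self):
        with pytest.raises(LagError):
            count_and_trim([DiscreteTrajectory([0, 1, 0])], 3)


class TestEstimateReversible:
    def test_symmetric_counts_closed_form(self):
        C = CountMatrix(np.array([[2.0, 1.0], [1.0, 2.0]]), 1, [0, 1])
        m = estimate_reversible(C)
        np.testing.assert_allclose(m.T, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]],
                                   atol=1e-10)
        assert m.pi == pytest.approx([0.5, 0.5])

    def test_disconnected_rejected(self):
        C = CountMatrix(np.diag([3.0, 2.0]), 1, [0, 1])
        with pytest.raises(ConnectivityError):
            estimate_reversible(C)

    def test_detailed_balance_random_counts(self, rng):
        C = CountMatrix(rng.integers(1, 30, size=(4, 4)).astype(float),
                        1, np.arange(4))
        m = estimate_reversible(C)
        flux = m.pi[:, None] * m.T
        assert np.max(np.abs(flux - flux.T)) < 1e-10
        assert m.T.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-12)

    def test_likelihood_beats_naive_symmetrization(self, rng):
        """Constrained MLE must dominate the (C+C^T)/2 heuristic estimate."""
        def loglik(T, C):
            mask = C > 0
            return float((C[mask] * np.log(T[mask])).sum())

        for seed in range(5):
            r = np.random.default_rng(seed)
            C = r.integers(1, 20, size=(4, 4)).astype(float)
            m = estimate_reversible(CountMatrix(C, 1, np.arange(4)))
            Cs = 0.5 * (C + C.T)
            T_naive = Cs / Cs.sum(axis=1, keepdims=True)
            assert loglik(m.T, C) >= loglik(T_naive, C) - 1e-9

    def test_matches_direct_likelihood_ascent(self, rng):
        """Cross-check the fixed point against brute-force optimization."""
        C = np.array([[8.0, 3.0, 1.0],
                      [2.0, 9.0, 4.0],
                      [2.0, 3.0, 7.0]])
        m = estimate_reversible(CountMatrix(C, 1, np.arange(3)))

        # brute force: parametrize symmetric flux x_ij >= 0, maximize
        # sum C_ij log(x_ij / x_i) over the 6 upper-triangle entries
        iu = np.triu_indices(3)

        def neg_loglik(params):
            X = np.zeros((3, 3))
            X[iu] = np.exp(params)
            X = X + np.triu(X, 1).T
            T = X / X.sum(axis=1, keepdims=True)
            return -(C * np.log(T)).sum()

        res = minimize(neg_loglik, np.zeros(len(iu[0])), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        X = np.zeros((3, 3))
        X[iu] = np.exp(res.x)
        X = X + np.triu(X, 1).T
        T_brute = X / X.sum(axis=1, keepdims=True)
        assert m.T == pytest.approx(T_brute, abs=5e-5)


class TestStationaryDistribution:
    def test_doubly_stochastic_uniform(self):
        T = TransitionMatrix(np.array([[0.5, 0.3, 0.2],
                                       [0.2, 0.5, 0.3],
                                       [0.3, 0.2, 0.5]]))
        assert stationary_distribution(T) == pytest.approx(np.ones(3) / 3)

    def test_two_state_hand_solution(self):
        T = TransitionMatrix(np.array([[0.9, 0.1], [0.2, 0.8]]))
        assert stationary_distribution(T) == pytest.approx([2 / 3, 1 / 3])

    def test_power_iteration_oracle(self, rng):
        M = rng.uniform(0.05, 1.0, size=(5, 5))
        M /= M.sum(axis=1, keepdims=True)
        T = TransitionMatrix(M)
        pi = stationary_distribution(T)
        p = np.ones(5) / 5
        for _ in range(20000):
            p = p @ T.matrix
        assert pi == pytest.approx(p, abs=1e-10)

    def test_reducible_rejected(self):
        T = TransitionMatrix(np.eye(2))
        with pytest.raises(ConnectivityError):
            stationary_distribution(T)


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        T = TransitionMatrix(np.array([[0.9, 0.1], [0.2, 0.8]]), lag=1)
        ts = implied_timescales_from_matrix(T)
        assert ts[0] == pytest.approx(-1.0 / np.log(0.7), abs=1e-10)

    def test_slow_limit_monotone_growth(self):
        prev = 0.0
        for eps in (0.2, 0.1, 0.05, 0.01):
            T = TransitionMatrix(np.array([[1 - eps, eps], [eps, 1 - eps]]))
            t = implied_timescales_from_matrix(T)[0]
            assert t > prev
            prev = t

    def test_recovery_from_simulated_dtrajs(self):
        T = np.array([[0.95, 0.05], [0.10, 0.90]])
        trajs, _ = kmc_ensemble(T, 0, n_traj=5, n_steps=20000, seed=9)
        dtrajs = [t.dtraj for t in trajs]
        ts = implied_timescales(dtrajs, [1])[1]
        expected = -1.0 / np.log(0.85)
        assert ts[0] == pytest.approx(expected, rel=0.10)


class TestPropagation:
    def test_stepwise_equals_power_form(self, funnel5):
        model, _ = funnel5
        p0 = np.zeros(5)
        p0[0] = 1.0
        step = propagate(p0, model.T, 7)
        power = p0 @ np.linalg.matrix_power(model.T, 7)
        assert step == pytest.approx(power, abs=1e-14)
        assert step.sum() == pytest.approx(1.0, abs=1e-12)

    def test_chapman_kolmogorov_small_scale(self):
        T = np.array([[0.8, 0.15, 0.05],
                      [0.1, 0.8, 0.1],
                      [0.05, 0.15, 0.8]])
        trajs, _ = kmc_ensemble(T, 0, n_traj=4, n_steps=50000, seed=5)
        dtrajs = [t.dtraj for t in trajs]
        C2, _ = count_and_trim(dtrajs, 2)
        T2 = estimate_reversible(C2).T
        assert np.max(np.abs(T2 - np.linalg.matrix_power(T, 2))) < 0.02


class TestTICA:
    @staticmethod
    def _slow_plus_noise(rng, n=4000, rho=0.99):
        slow = np.empty(n)
        slow[0] = 0.0
        eps = rng.normal(size=n)
        for t in range(1, n):
            slow[t] = rho * slow[t - 1] + np.sqrt(1 - rho ** 2) * eps[t]
        noise = rng.normal(size=n)
        return np.column_stack([slow, noise])

    def test_first_tic_finds_slow_direction(self, rng):
        X = self._slow_plus_noise(rng)
        proj = tica_project(X, lag=10, n_components=1)
        # projection must be (anti)aligned with the slow coordinate
        c = np.corrcoef(proj.values[:, 0], X[:, 0])[0, 1]
        assert abs(c) > 0.99

    def test_rotation_invariant_eigenvalues(self, rng):
        X = self._slow_plus_noise(rng)
        theta = 0.77
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        p1 = tica_project(X, lag=5, n_components=2)
        p2 = tica_project(X @ R.T, lag=5, n_components=2)
        # autocorrelations of the recovered components match
        def acf(v, lag=5):
            v = v - v.mean()
            return float((v[:-lag] * v[lag:]).mean() / v.var())
        for k in range(2):
            assert acf(p1.values[:, k]) == pytest.approx(
                acf(p2.values[:, k]), abs=1e-6)

    def test_lag_validation(self, rng):
        with pytest.raises(LagError):
            tica_project(rng.normal(size=(10, 2)), lag=10, n_components=1)


class TestTransitionMatrixInvariants:
    def test_row_sum_enforced(self):
        with pytest.raises(MatrixError):
            TransitionMatrix(np.array([[0.5, 0.4], [0.5, 0.5]]))

    def test_funnel_pi_is_boltzmann(self, funnel5):
        model, _ = funnel5
        assert stationary_distribution(model.tmatrix) == pytest.approx(
            model.pi, abs=1e-10)
        assert model.pi @ model.T == pytest.approx(model.pi, abs=1e-10)
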