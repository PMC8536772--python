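import numpy as np
import pytest

from mmsgait.causality import (CovarianceSet, build_network, detect_feedback,
                               gc_significance, gc_single_lag,
                               group_feedback_map, lag_sweep, sample_moments)
from mmsgait.synthetic import simulate_coupled_pair

from _gc_oracle import solve_moment_equations


def random_covariance(rng):
    """A random covariance set with positive-definite zero-lag block."""
    a = rng.normal(size=(2, 2))
    zero_lag = a @ a.T + 0.1 * np.eye(2)
    return CovarianceSet(
        Rxx0=zero_lag[0, 0], Ryy0=zero_lag[1, 1], Rxy0=zero_lag[0, 1],
        Rxxl=rng.normal(scale=np.sqrt(zero_lag[0, 0])),
        Rxyl=rng.normal(scale=np.sqrt(zero_lag[1, 1])), lag=1)


HAND_COV = CovarianceSet(Rxx0=2.0, Rxxl=1.0, Ryy0=1.0, Rxy0=0.25, Rxyl=0.5,
                         lag=1)


class TestSampleMoments:
    def test_identity_pair(self, rng):
        x = rng.normal(size=500)
        cov = sample_moments(x, x, 2)
        assert cov.Rxy0 == pytest.approx(cov.Rxx0)

    def test_hand_series(self):
        x = np.array([1.0, -1.0, 1.0, -1.0] * 4)
        cov = sample_moments(x, x, 1)
        assert cov.Rxx0 == pytest.approx(1.0)
        assert cov.Rxxl == pytest.approx(-1.0)

    def test_white_noise_lag_moment_vanishes(self, rng):
        n = 100_000
        x = rng.normal(size=n)
        cov = sample_moments(x, rng.normal(size=n), 5)
        assert abs(cov.Rxxl) < 3 / np.sqrt(n)

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            sample_moments(np.ones(5), np.ones(5), 3)


class TestGCSingleLag:
    def test_matches_symbolic_solver_on_1000_random_sets(self, rng):
        for _ in range(1000):
            cov = random_covariance(rng)
            if abs(cov.Rxxl) < 1e-6:
                continue
            res = gc_single_lag(cov, "paper", "permissive")
            a1, a2, b, s1, s2, gc = solve_moment_equations(
                cov.Rxx0, cov.Rxxl, cov.Ryy0, cov.Rxy0, cov.Rxyl)
            if res.a1 is None:      # singular system flagged
                continue
            # tolerance scaled by the magnitude of the summed terms, so the
            # 1e-10 agreement is meaningful even for ill-conditioned systems
            assert res.a1 == pytest.approx(a1, rel=1e-10, abs=1e-12)
            assert res.a2 == pytest.approx(a2, rel=1e-10,
                                           abs=1e-10 * (1 + abs(b)))
            assert res.b == pytest.approx(b, rel=1e-10,
                                          abs=1e-10 * (1 + abs(a2)))
            s1_terms = (1 + a1 ** 2) * cov.Rxx0
            s2_terms = ((1 + a2 ** 2) * cov.Rxx0 + b ** 2 * cov.Ryy0
                        + 2 * abs(a2 * b * cov.Rxy0))
            assert res.sigma1_sq == pytest.approx(s1, abs=1e-10 * s1_terms)
            assert res.sigma2_sq == pytest.approx(s2, abs=1e-10 * s2_terms)
            if gc is not None and res.gc is not None:
                assert res.gc == pytest.approx(
                    gc, abs=1e-10 * (1 + s2_terms / abs(s2)))

    def test_hand_example_paper_mode(self):
        res = gc_single_lag(HAND_COV, "paper", "permissive")
        assert res.a1 == pytest.approx(2.0)
        assert res.a2 == pytest.approx(0.0, abs=1e-14)
        assert res.b == pytest.approx(4.0)
        assert res.sigma1_sq == pytest.approx(-6.0)
        assert res.sigma2_sq == pytest.approx(-14.0)
        assert res.gc == pytest.approx(np.log(3 / 7))

    def test_hand_example_strict_policy_invalid(self):
        res = gc_single_lag(HAND_COV, "paper", "strict")
        assert not res.valid
        assert res.gc is None

    def test_hand_example_confirmed_by_oracle(self):
        a1, a2, b, s1, s2, gc = solve_moment_equations(2, 1, 1, 0.25, 0.5)
        assert (a1, a2, b) == pytest.approx((2.0, 0.0, 4.0))
        assert (s1, s2) == pytest.approx((-6.0, -14.0))
        assert gc == pytest.approx(np.log(3 / 7))

    def test_ols_mode_independent_pair_gc_near_zero(self, rng):
        n = 100_000
        cov = sample_moments(rng.normal(size=n), rng.normal(size=n), 3)
        res = gc_single_lag(cov, "ols", "strict")
        assert abs(res.b) < 0.02
        assert abs(res.gc) < 0.01

    def test_ols_mode_near_perfect_shift_gives_large_gc(self, rng):
        y = rng.normal(size=5000)
        lag = 4
        x = np.concatenate([rng.normal(size=lag), y[:-lag]])
        x = x + rng.normal(scale=0.01, size=len(x))
        cov = sample_moments(x, y, lag)
        res = gc_single_lag(cov, "ols", "strict")
        assert res.sigma2_sq < 0.001 * res.sigma1_sq
        assert res.gc > 1.0

    def test_paper_mode_zero_rxxl_invalid(self):
        cov = CovarianceSet(Rxx0=1.0, Rxxl=0.0, Ryy0=1.0, Rxy0=0.1, Rxyl=0.1)
        res = gc_single_lag(cov, "paper", "strict")
        assert not res.valid and "a1" in res.reason

    def test_collinear_system_flagged(self):
        cov = CovarianceSet(Rxx0=1.0, Rxxl=0.5, Ryy0=0.25, Rxy0=0.5,
                            Rxyl=0.25)
        res = gc_single_lag(cov, "paper", "strict")
        assert not res.valid and res.reason == "collinear"

    def test_ols_gc_nonnegative_up_to_noise(self, rng):
        n = 100_000
        for _ in range(5):
            cov = sample_moments(rng.normal(size=n), rng.normal(size=n), 2)
            res = gc_single_lag(cov, "ols", "strict")
            assert res.gc > -0.01


class TestLagSweep:
    def test_singleton_range(self, rng):
        x, y = simulate_coupled_pair(500, seed=rng)
        sweep = lag_sweep(x, y, [3], mode="ols")
        assert sweep.optimal_lag == 3

    def test_force_is_max_gc_over_lag(self):
        x, y = simulate_coupled_pair(2000, lag=3, seed=0)
        sweep = lag_sweep(x, y, range(1, 11), mode="ols")
        assert sweep.force == pytest.approx(sweep.max_gc / sweep.optimal_lag)

    def test_recovers_planted_lag(self):
        hits = 0
        for seed in range(20):
            x, y = simulate_coupled_pair(20_000, a2=0.5, b=0.4, lag=3,
                                         seed=seed)
            sweep = lag_sweep(x, y, range(1, 11), mode="ols")
            hits += sweep.optimal_lag == 3
        assert hits >= 18

    def test_ols_parameter_recovery(self):
        x, y = simulate_coupled_pair(100_000, a2=0.5, b=0.4, lag=3, seed=11)
        cov = sample_moments(x, y, 3)
        res = gc_single_lag(cov, "ols", "strict")
        assert res.a2 == pytest.approx(0.5, abs=0.02)
        assert res.b == pytest.approx(0.4, abs=0.02)

    def test_empty_range_errors(self):
        with pytest.raises(ValueError, match="empty lag range"):
            lag_sweep(np.ones(100), np.ones(100), [])

    def test_force_decreasing_in_lag_at_fixed_gc(self):
        # analytic: force = gc / lag
        gc = 0.6
        forces = [gc / lag for lag in range(1, 10)]
        assert all(a > b for a, b in zip(forces, forces[1:]))


class TestSignificance:
    def test_p_bounds(self, rng):
        x, y = simulate_coupled_pair(400, b=0.0, seed=rng)
        sweep = lag_sweep(x, y, range(1, 6), mode="ols")
        sig = gc_significance(x, y, sweep, n_surrogates=99, seed=1)
        assert 1 / 100 <= sig.p_value <= 1.0

    def test_strong_coupling_minimal_p(self):
        x, y = simulate_coupled_pair(2000, a2=0.3, b=0.6, lag=2, seed=3)
        sweep = lag_sweep(x, y, range(1, 8), mode="ols")
        sig = gc_significance(x, y, sweep, alpha=0.01, n_surrogates=99,
                              seed=4)
        assert sig.p_value == pytest.approx(1 / 100)
        assert sig.significant

    def test_too_few_surrogates_rejected(self):
        x, y = simulate_coupled_pair(400, seed=0)
        sweep = lag_sweep(x, y, range(1, 4), mode="ols")
        with pytest.raises(ValueError, match="at least 99"):
            gc_significance(x, y, sweep, n_surrogates=10)

    def test_short_series_rejected(self):
        x, y = simulate_coupled_pair(400, seed=0)
        sweep = lag_sweep(x, y, range(1, 26), mode="ols")
        with pytest.raises(ValueError, match="too short"):
            gc_significance(x[:80], y[:80], sweep, n_surrogates=99)


class TestFeedbackAndNetwork:
    @staticmethod
    def _edge(x, y, seed):
        sweep = lag_sweep(x, y, range(1, 6), mode="ols")
        sig = gc_significance(x, y, sweep, alpha=0.01, n_surrogates=99,
                              seed=seed)
        return sweep, sig

    def test_unidirectional_coupling_not_feedback(self):
        x, y = simulate_coupled_pair(1500, a2=0.2, b=0.5, lag=2, seed=5)
        s_xy, g_xy = self._edge(x, y, 10)   # y -> x direction (true)
        s_yx, g_yx = self._edge(y, x, 11)   # x -> y direction (absent)
        assert not detect_feedback(s_xy, s_yx, g_xy, g_yx)

    def test_bidirectional_coupling_is_feedback(self):
        x, y = simulate_coupled_pair(1500, a2=0.1, b=0.5, lag=2, b_back=0.5,
                                     seed=6)
        s_xy, g_xy = self._edge(x, y, 12)
        s_yx, g_yx = self._edge(y, x, 13)
        assert detect_feedback(s_xy, s_yx, g_xy, g_yx)

    def _star_network(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 1500
        hub = rng.normal(size=n)
        leaves = {}
        for i in range(2):
            w = rng.normal(size=n)
            leaf = w.copy()
            leaf[2:] += 0.6 * hub[:-2]
            leaves[f"leaf{i}"] = leaf
        series = {"hub": hub, **leaves}
        nodes = list(series)
        sweeps, sigs = {}, {}
        rng2 = np.random.default_rng(seed + 1)
        for a in nodes:
            for b in nodes:
                if a == b:
                    continue
                sw = lag_sweep(series[b], series[a], range(1, 6), mode="ols")
                sg = gc_significance(series[b], series[a], sw, alpha=0.01,
                                     n_surrogates=99, seed=rng2)
                sweeps[(a, b)] = sw
                sigs[(a, b)] = sg
        return build_network(nodes, sweeps, sigs)

    def test_star_out_degrees_and_no_feedback(self):
        net = self._star_network(seed=21)
        assert net.out_degree["hub"] == 2
        assert net.out_degree["leaf0"] == 0
        assert net.out_degree["leaf1"] == 0
        assert not net.feedback_pairs

    def test_symmetric_gc_zero_asymmetry(self):
        from mmsgait.causality import CausalEdge, LagSweep

        nodes = ["a", "b"]
        sweeps, sigs = {}, {}
        for pair in [("a", "b"), ("b", "a")]:
            sweeps[pair] = LagSweep(
                lags=np.array([1]), gc=np.array([0.5]), results=[],
                estimator_mode="ols", validity_policy="strict",
                optimal_lag=1, max_gc=0.5)
            from mmsgait.causality import SignificanceResult
            sigs[pair] = SignificanceResult(0.01, True, 0.5, 99)
        net = build_network(nodes, sweeps, sigs)
        assert net.asymmetry_index == pytest.approx(0.0)
        assert net.feedback_pairs == {frozenset(("a", "b"))}

    def test_missing_pair_errors(self):
        with pytest.raises(ValueError, match="missing pairwise sweeps"):
            build_network(["a", "b"], {}, {})


class TestGroupFeedbackMap:
    @staticmethod
    def _net(nodes, pairs):
        from mmsgait.causality import CausalNetwork
        return CausalNetwork(nodes=nodes, edges={},
                             feedback_pairs={frozenset(p) for p in pairs})

    def test_half_prevalence(self):
        nets = [self._net(["a", "b"], [("a", "b")]),
                self._net(["a", "b"], [])]
        mat = group_feedback_map(nets)
        assert mat.loc["a", "b"] == pytest.approx(50.0)

    def test_no_feedback_zero_matrix(self):
        nets = [self._net(["a", "b"], []) for _ in range(3)]
        assert (group_feedback_map(nets).to_numpy() == 0).all()

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty group"):
            group_feedback_map([])
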