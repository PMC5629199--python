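"""Adaptive-sampling engine: seed strategies, rounds, first-passage grids."""

import numpy as np
import pytest

from ecsampler.adaptive import (AdaptiveRunConfig, MSMSampler, adaptive_run,
                                fpt_grid, select_seeds, NOT_REACHED)
from ecsampler.fixtures import generate_guided_landscape


class TestSelectSeeds:
    @pytest.fixture
    def clusters(self):
        return {0: [np.array(10)], 1: [np.array(11)], 2: [np.array(12)]}

    def test_max_score_ordering(self, clusters):
        scores = {0: 1.0, 1: 2.0, 2: 3.0}
        seeds = select_seeds(clusters, "max_score", 2, scores=scores,
                             rng=np.random.default_rng(0))
        assert [int(s) for s in seeds] == [12, 11]

    def test_min_score_ordering(self, clusters):
        scores = {0: 1.0, 1: 2.0, 2: 3.0}
        seeds = select_seeds(clusters, "min_score", 2, scores=scores,
                             rng=np.random.default_rng(0))
        assert [int(s) for s in seeds] == [10, 11]

    def test_lowest_count(self):
        clusters = {0: [0] * 7, 1: [1] * 2, 2: [2] * 5}
        seeds = select_seeds(clusters, "lowest_count", 1,
                             rng=np.random.default_rng(0))
        assert seeds == [1]

    def test_random_deterministic(self, clusters):
        a = select_seeds(clusters, "random", 2, rng=np.random.default_rng(5))
        b = select_seeds(clusters, "random", 2, rng=np.random.default_rng(5))
        assert [int(x) for x in a] == [int(x) for x in b]

    def test_fewer_clusters_than_seeds_warns(self, clusters):
        with pytest.warns(UserWarning, match="replacement"):
            seeds = select_seeds(clusters, "random", 7,
                                 rng=np.random.default_rng(1))
        assert len(seeds) == 7

    def test_score_strategy_requires_scores(self, clusters):
        with pytest.raises(ValueError):
            select_seeds(clusters, "max_score", 1,
                         rng=np.random.default_rng(0))


def _landscape_sampler(n_states=50, seed=0):
    land = generate_guided_landscape(n_states=n_states, seed=seed)
    return MSMSampler(land.model.T, land.score, land.target, land.start)


class TestAdaptiveRun:
    def test_target_equal_start_hits_at_zero_time(self):
        land = generate_guided_landscape(seed=2)
        s = MSMSampler(land.model.T, land.score, {land.start}, land.start)
        rep = adaptive_run(s, AdaptiveRunConfig(n_parallel=3, traj_length=5,
                                                n_rounds=2, seed=0))
        assert rep.hit and rep.hit_round == 1 and rep.hit_frame == 0
        assert rep.total_time == 0.0

    def test_identity_dynamics_never_reached(self):
        n = 12
        s = MSMSampler(np.eye(n), np.arange(n, 0, -1.0), {n - 1}, 0)
        rep = adaptive_run(s, AdaptiveRunConfig(n_parallel=4, traj_length=10,
                                                n_rounds=3, seed=1))
        assert not rep.hit
        assert rep.total_time == NOT_REACHED
        assert rep.n_rounds_run == 3

    def test_accounting_identity(self):
        """total_time == completed trajectories x S + hitting frame."""
        s = _landscape_sampler(seed=4)
        cfg = AdaptiveRunConfig(n_parallel=7, traj_length=31, n_rounds=80,
                                strategy="min_score", seed=3)
        rep = adaptive_run(s, cfg)
        assert rep.hit
        completed = (rep.hit_round - 1) * 7 + rep.hit_trajectory
        assert rep.total_time == completed * 31 + rep.hit_frame
        # the hitting frame really is inside the target
        seg = rep.rounds[-1].segments[rep.hit_trajectory]
        assert seg.first_hit() == rep.hit_frame

    def test_deterministic_per_seed(self):
        cfg = AdaptiveRunConfig(n_parallel=5, traj_length=20, n_rounds=40,
                                strategy="min_score", seed=9)
        a = adaptive_run(_landscape_sampler(seed=1), cfg)
        b = adaptive_run(_landscape_sampler(seed=1), cfg)
        assert a.total_time == b.total_time
        assert a.hit_round == b.hit_round

    def test_guided_beats_random_on_funnel(self):
        """Paired replicates: guided median hit round <= random median."""
        guided, random_ = [], []
        for rep in range(20):
            seed = 1000 + rep
            cfg_g = AdaptiveRunConfig(n_parallel=10, traj_length=50,
                                      n_rounds=60, strategy="min_score",
                                      seed=seed)
            cfg_r = AdaptiveRunConfig(n_parallel=10, traj_length=50,
                                      n_rounds=60, strategy="random",
                                      seed=seed)
            s = _landscape_sampler(seed=0)
            guided.append(adaptive_run(s, cfg_g).total_time)
            random_.append(adaptive_run(s, cfg_r).total_time)
        assert np.median(guided) <= np.median(random_)

    def test_lowest_count_strategy_runs(self):
        s = _landscape_sampler(seed=5)
        cfg = AdaptiveRunConfig(n_parallel=6, traj_length=25, n_rounds=10,
                                strategy="lowest_count", seed=2)
        rep = adaptive_run(s, cfg)
        assert rep.n_rounds_run <= 10

    def test_frame_filter_excludes_from_clustering(self):
        # filter out every state above 25: seeds can then only come from
        # the allowed half of the chain
        s = _landscape_sampler(seed=6)
        cfg = AdaptiveRunConfig(n_parallel=4, traj_length=10, n_rounds=4,
                                strategy="random", seed=7,
                                frame_filter=lambda f: int(f) <= 25)
        rep = adaptive_run(s, cfg)
        for rr in rep.rounds[1:]:
            assert all(int(x) <= 25 for x in rr.seeds)


class TestMSMUnbiasedness:
    def test_msm_from_adaptive_data_recovers_pi(self):
        """Sampling bias from reseeding is removed by MSM re-estimation."""
        from ecsampler.fixtures import FunnelChainSpec, generate_msm
        from ecsampler.msm import (DiscreteTrajectory, count_and_trim,
                                   estimate_reversible)
        spec = FunnelChainSpec(n_states=8, barrier=1.0, seed=11)
        model, coord = generate_msm(spec)
        # empty target: the run never stops early, so every round's data is
        # produced under genuinely biased (reseeded) sampling
        s = MSMSampler(model.T, coord, (), spec.start)
        cfg = AdaptiveRunConfig(n_parallel=10, traj_length=4000, n_rounds=8,
                                strategy="lowest_count", seed=13)
        rep = adaptive_run(s, cfg)
        assert not rep.hit and rep.n_rounds_run == 8
        dtrajs = [DiscreteTrajectory(seg.frames)
                  for rr in rep.rounds for seg in rr.segments]
        C, active = count_and_trim(dtrajs, 1)
        est = estimate_reversible(C)
        assert len(active) == 8
        np.testing.assert_allclose(est.pi, model.pi, atol=0.02)


class TestFPTGrid:
    def test_immediate_absorption_serial(self):
        T = np.array([[0.0, 1.0], [0.0, 1.0]])

        def factory():
            return MSMSampler(T, np.array([1.0, 0.0]), {1}, 0)

        grid = fpt_grid(factory, "serial", S_values=[1], count_values=[4, 8],
                        replicates=2, seed=0)
        # the first launched trajectory hits on its first step
        assert np.all(grid.median_total_time == 1.0)
        assert np.all(grid.hit_fraction == 1.0)

    def test_guided_reaches_where_serial_fails(self):
        def factory():
            return _landscape_sampler(seed=0)

        S, counts = [5], [40]
        g = fpt_grid(factory, "guided_adaptive", S, counts, replicates=3,
                     seed=2, n_parallel=10)
        s = fpt_grid(factory, "serial", S, counts, replicates=3, seed=2)
        assert g.hit_fraction[0, 0] >= s.hit_fraction[0, 0]
        assert g.median_total_time[0, 0] <= s.median_total_time[0, 0]

    def test_rows_export(self):
        T = np.array([[0.0, 1.0], [0.0, 1.0]])

        def factory():
            return MSMSampler(T, np.array([1.0, 0.0]), {1}, 0)

        grid = fpt_grid(factory, "serial", [1, 2], [3], replicates=1, seed=1)
        rows = grid.to_rows()
        assert len(rows) == 2
        assert rows[0][:2] == (1, 3)

    def test_unknown_protocol(self):
        with pytest.raises(ValueError):
            fpt_grid(lambda: None, "steered", [1], [1])
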