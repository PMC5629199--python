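"""The adaptive-sampling engine: rounds, seed strategies, first-passage grids.

Adaptive sampling runs N short unbiased trajectories in parallel, clusters
the frames sampled so far on a structural metric, picks n seed clusters by
a strategy, and launches the next round from representatives of those
clusters.  No bias enters the dynamics -- only the choice of starting
points -- so a Markov state model built on the pooled data can still
recover equilibrium properties.

Seed strategies
---------------
``random``              clusters drawn uniformly without replacement
``lowest_count``        least-populated clusters (classic count-based rule)
``max_score``           clusters with the largest guidance score (explore
                        away from a reference, e.g. maximize dSEC)
``min_score``           clusters with the smallest guidance score (fold or
                        associate toward coupled-pair contacts)
``min_target_distance`` alias of ``min_score`` for distance-to-target scores

Samplers are pluggable through a small adapter contract
(:class:`MSMSampler` for kinetic Monte Carlo on a transition matrix,
:class:`BrownianSampler` for the 2-D benchmark); a molecular-dynamics
engine could be wired in behind the same contract.

Accounting: the total simulation time at first target hit is the number of
trajectories completed before the hitting one times the trajectory length,
plus the frames of the hitting trajectory up to and including the hitting
frame, in frame units (tau for discrete samplers, integrator steps for
Brownian ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .brownian import BrownianParams, Potential2D, simulate_batch
from .errors import ECSamplerError
from .msm import TransitionMatrix

__all__ = [
    "SeedStrategy",
    "AdaptiveRunConfig",
    "TrajectorySegment",
    "RoundRecord",
    "AdaptiveReport",
    "FPTGridResult",
    "MSMSampler",
    "BrownianSampler",
    "select_seeds",
    "adaptive_run",
    "fpt_grid",
]

STRATEGIES = ("random", "lowest_count", "max_score", "min_score",
              "min_target_distance")
NOT_REACHED = np.inf  # sentinel for cells whose budget ran out


@dataclass(frozen=True)
class AdaptiveRunConfig:
    """Protocol parameters: N parallel trajectories of length S, R rounds.

    ``n_clusters`` bounds the clustering used for seed selection;
    ``score_samples`` is how many member frames are averaged into a cluster
    guidance score (50, matching cluster-scoring practice).
    ``frame_filter``, when given, excludes frames (e.g. separated-monomer
    frames beyond a center-of-mass cutoff) from clustering only -- target
    detection still sees every frame.  ``cluster_pool`` is "cumulative"
    (cluster all frames sampled so far) or "round" (current round only).
    """

    n_parallel: int = 10
    traj_length: int = 100
    n_rounds: int = 10
    n_clusters: int = 100
    strategy: str = "random"
    seed: int = 0
    score_samples: int = 50
    cluster_pool: str = "cumulative"
    cluster_stride: int = 1
    frame_filter: Optional[Callable] = None

    def __post_init__(self):
        if min(self.n_parallel, self.traj_length, self.n_rounds,
               self.n_clusters) < 1:
            raise ValueError("N, S, R and k must all be >= 1")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.cluster_pool not in ("cumulative", "round"):
            raise ValueError("cluster_pool must be 'cumulative' or 'round'")


@dataclass
class TrajectorySegment:
    """One trajectory of one round: frames, guidance scores, target flags."""

    frames: np.ndarray        # (L+1,) int states or (L+1, d) float coords
    scores: np.ndarray        # (L+1,) guidance score per frame
    hits: np.ndarray          # (L+1,) bool, target membership per frame

    def first_hit(self) -> Optional[int]:
        idx = np.flatnonzero(self.hits)
        return int(idx[0]) if idx.size else None


@dataclass
class RoundRecord:
    round_index: int
    seeds: list
    segments: List[TrajectorySegment]


@dataclass
class AdaptiveReport:
    """Outcome of one adaptive run."""

    hit: bool
    hit_round: Optional[int]
    hit_trajectory: Optional[int]
    hit_frame: Optional[int]
    total_time: float          # frame units; NOT_REACHED if budget exhausted
    rounds: List[RoundRecord]

    @property
    def n_rounds_run(self):
        return len(self.rounds)


@dataclass
class FPTGridResult:
    """Median total time to first hit over an (S, count) protocol grid."""

    protocol: str
    S_values: np.ndarray
    count_values: np.ndarray          # trajectories for serial, rounds-axis total for adaptive
    median_total_time: np.ndarray     # (len(S), len(count)); NOT_REACHED sentinel
    hit_fraction: np.ndarray
    replicates: int

    def to_rows(self):
        """Flat (S, count, median_total_time, hit_fraction) rows for CSV."""
        rows = []
        for i, s in enumerate(self.S_values):
            for j, c in enumerate(self.count_values):
                rows.append((s, c, self.median_total_time[i, j],
                             self.hit_fraction[i, j]))
        return rows


class MSMSampler:
    """Kinetic Monte Carlo sampler over a transition matrix.

    ``score`` is a per-state guidance value (a dSEC-like coordinate);
    ``target`` is the set of target states.  Frames are state labels, and
    clustering is the identity on labels (microstates are the clusters).
    """

    discrete = True

    def __init__(self, T, score: Sequence[float], target: Iterable[int],
                 start: int):
        self.T = T.matrix if isinstance(T, TransitionMatrix) else np.asarray(T, float)
        self.cum = np.cumsum(self.T, axis=1)
        self.score_by_state = np.asarray(score, float)
        self.target = frozenset(int(t) for t in target)
        self.start = int(start)
        # a start inside the target is allowed: the adaptive run then hits
        # on frame 0 of round 1 at zero simulation time

    def initial_seed(self):
        return self.start

    def run(self, seed_frame, n_steps: int, rng: np.random.Generator):
        states = np.empty(n_steps + 1, dtype=np.int64)
        states[0] = int(seed_frame)
        u = rng.random(n_steps)
        s = int(seed_frame)
        for t in range(n_steps):
            s = int(np.searchsorted(self.cum[s], u[t], side="right"))
            states[t + 1] = s
        hits = np.isin(states, list(self.target))
        return TrajectorySegment(frames=states,
                                 scores=self.score_by_state[states],
                                 hits=hits)

    def run_batch(self, seeds, n_steps, rng_list):
        return [self.run(s, n_steps, rng) for s, rng in zip(seeds, rng_list)]


class BrownianSampler:
    """Euler-Maruyama sampler on a 2-D potential.

    The guidance score of a frame is its Euclidean distance to the target
    well center; a frame within ``target_radius`` of it is a hit.
    """

    discrete = False

    def __init__(self, potential: Potential2D, params: BrownianParams,
                 target_radius: float = 0.4):
        self.potential = potential
        self.params = params
        self.target_radius = float(target_radius)

    def initial_seed(self):
        return self.potential.start

    def _segment(self, traj: np.ndarray) -> TrajectorySegment:
        d = np.linalg.norm(traj - self.potential.target, axis=-1)
        return TrajectorySegment(frames=traj, scores=d,
                                 hits=d <= self.target_radius)

    def run(self, seed_frame, n_steps, rng):
        bp = BrownianParams(self.params.diffusion, self.params.dt,
                            self.params.kT, n_steps, self.params.seed)
        traj = simulate_batch(self.potential, bp,
                              np.asarray(seed_frame, float)[None, :], rng)[0]
        return self._segment(traj)

    def run_batch(self, seeds, n_steps, rng_list):
        # one pre-drawn noise block per trajectory, so the ensemble equals
        # independent runs under the same per-trajectory streams
        from .brownian import _integrate
        bp = BrownianParams(self.params.diffusion, self.params.dt,
                            self.params.kT, n_steps, self.params.seed)
        X0 = np.asarray([np.asarray(s, float) for s in seeds])
        noise = np.stack([rng.standard_normal((n_steps, 2))
                          for rng in rng_list])
        out = _integrate(self.potential, bp, X0, noise)
        return [self._segment(out[i]) for i in range(out.shape[0])]


def select_seeds(clusters: Dict[int, list], strategy: str, n_seeds: int,
                 scores: Optional[Dict[int, float]] = None,
                 counts: Optional[Dict[int, int]] = None,
                 rng: Optional[np.random.Generator] = None) -> list:
    """Pick seed frames: one random representative from each chosen cluster.

    ``clusters`` maps cluster label to its member frames.  max_score /
    min_score rank clusters by the guidance score, lowest_count by
    population ascending, random draws uniformly without replacement; all
    ties break toward the lower cluster label.  If there are fewer clusters
    than seeds requested, clusters are reused (sampling with replacement)
    after a warning.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not clusters:
        raise ECSamplerError("no clusters to select seeds from")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    labels = sorted(clusters)
    if strategy in ("max_score", "min_score", "min_target_distance"):
        if scores is None:
            raise ValueError(f"strategy {strategy!r} needs cluster scores")
        sign = -1.0 if strategy == "max_score" else 1.0
        ranked = sorted(labels, key=lambda c: (sign * scores[c], c))
    elif strategy == "lowest_count":
        if counts is None:
            counts = {c: len(clusters[c]) for c in labels}
        ranked = sorted(labels, key=lambda c: (counts[c], c))
    else:  # random
        ranked = list(rng.permutation(labels))
    if len(ranked) < n_seeds:
        warnings.warn(
            f"only {len(ranked)} clusters for {n_seeds} seeds; "
            "sampling clusters with replacement", stacklevel=2)
        chosen = list(ranked) + [ranked[int(i)] for i in
                                 rng.integers(0, len(ranked),
                                              n_seeds - len(ranked))]
    else:
        chosen = ranked[:n_seeds]
    seeds = []
    for c in chosen:
        members = clusters[c]
        seeds.append(members[int(rng.integers(0, len(members)))])
    return seeds


def _cluster_scores(clusters, frame_scores, n_samples, rng):
    """Guidance score per cluster: mean over up to n_samples random members."""
    out = {}
    for c, members in clusters.items():
        sc = frame_scores[c]
        take = min(n_samples, len(sc))
        idx = rng.choice(len(sc), size=take, replace=False)
        out[c] = float(np.mean([sc[i] for i in idx]))
    return out


def adaptive_run(sampler, cfg: AdaptiveRunConfig) -> AdaptiveReport:
    """Run rounds of sample -> cluster -> reseed until the target is hit.

    Round r launches ``cfg.n_parallel`` trajectories of ``cfg.traj_length``
    frames from the current seeds (round 1 starts every trajectory from the
    sampler's initial seed).  Target membership is checked on every frame;
    on the first hit the run stops and reports hitting round, trajectory,
    frame, and the exact total simulation time.  Otherwise frames are
    pooled per ``cfg.cluster_pool``, clustered, scored, and
    ``cfg.strategy`` picks the next seeds.
    """
    N, S, R = cfg.n_parallel, cfg.traj_length, cfg.n_rounds
    seeds = [sampler.initial_seed() for _ in range(N)]
    select_rng = np.random.default_rng([cfg.seed, 0xA5])
    pool_frames: list = []   # one array per trajectory segment
    pool_scores: list = []
    rounds: List[RoundRecord] = []
    for r in range(1, R + 1):
        rngs = [np.random.default_rng([cfg.seed, r, i]) for i in range(N)]
        if hasattr(sampler, "run_batch"):
            segments = sampler.run_batch(seeds, S, rngs)
        else:
            segments = [sampler.run(s, S, rng) for s, rng in zip(seeds, rngs)]
        rounds.append(RoundRecord(r, list(seeds), segments))
        for i, seg in enumerate(segments):
            h = seg.first_hit()
            if h is not None:
                completed = (r - 1) * N + i
                return AdaptiveReport(
                    hit=True, hit_round=r, hit_trajectory=i, hit_frame=h,
                    total_time=float(completed * S + h), rounds=rounds)
        new_frames, new_scores = [], []
        for seg in segments:
            frames, scores_ = seg.frames, seg.scores
            if cfg.frame_filter is not None:
                keep = np.asarray([bool(cfg.frame_filter(f)) for f in frames])
                frames, scores_ = frames[keep], scores_[keep]
            new_frames.append(frames)
            new_scores.append(scores_)
        if cfg.cluster_pool == "cumulative":
            pool_frames.extend(new_frames)
            pool_scores.extend(new_scores)
        else:
            pool_frames, pool_scores = new_frames, new_scores
        if r == R:
            break
        F = np.concatenate(pool_frames)[::cfg.cluster_stride]
        V = np.concatenate(pool_scores)[::cfg.cluster_stride]
        if F.shape[0] == 0:
            raise ECSamplerError(
                f"round {r}: frame filter removed every frame; cannot reseed")
        clusters_idx: Dict[int, np.ndarray] = {}
        if sampler.discrete:
            for lab in np.unique(F):
                clusters_idx[int(lab)] = np.flatnonzero(F == lab)
        else:
            k_eff = min(cfg.n_clusters, F.shape[0])
            km = KMeans(n_clusters=k_eff, n_init=3,
                        random_state=int(select_rng.integers(2 ** 31))).fit(F)
            for lab in range(k_eff):
                idx = np.flatnonzero(km.labels_ == lab)
                if idx.size:
                    clusters_idx[int(lab)] = idx
        clusters = {c: F[idx] for c, idx in clusters_idx.items()}
        frame_scores = {c: V[idx] for c, idx in clusters_idx.items()}
        scores = _cluster_scores(clusters, frame_scores, cfg.score_samples,
                                 select_rng)
        counts = {c: len(idx) for c, idx in clusters_idx.items()}
        seeds = select_seeds(clusters, cfg.strategy, N, scores=scores,
                             counts=counts, rng=select_rng)
    return AdaptiveReport(hit=False, hit_round=None, hit_trajectory=None,
                          hit_frame=None, total_time=NOT_REACHED,
                          rounds=rounds)


def _serial_run(sampler, n_traj: int, length: int, seed: int) -> float:
    """Serial protocol: n_traj independent trajectories, launch-order time."""
    start = sampler.initial_seed()
    rngs = [np.random.default_rng([seed, 1, i]) for i in range(n_traj)]
    if hasattr(sampler, "run_batch"):
        segments = sampler.run_batch([start] * n_traj, length, rngs)
    else:
        segments = [sampler.run(start, length, rng) for rng in rngs]
    for i, seg in enumerate(segments):
        h = seg.first_hit()
        if h is not None:
            return float(i * length + h)
    return NOT_REACHED


def fpt_grid(sampler_factory, protocol: str, S_values, count_values,
             replicates: int = 1, seed: int = 0, n_parallel: int = 10,
             n_clusters: int = 100, strategy: Optional[str] = None,
             cluster_stride: int = 1) -> FPTGridResult:
    """First-passage grid over trajectory length S and trajectory count.

    ``sampler_factory`` is a zero-argument callable returning a fresh
    sampler (so replicate cells stay independent).  For the ``serial``
    protocol the count axis is the number of parallel trajectories; for
    ``random_adaptive`` and ``guided_adaptive`` it is the total number of
    trajectories N x R with N fixed at ``n_parallel`` (counts are rounded
    down to whole rounds, minimum one).  Each cell records the median total
    simulation time over ``replicates`` independent repeats, with the
    not-reached sentinel (inf) entering the median as an exhausted budget.
    """
    if protocol not in ("serial", "random_adaptive", "guided_adaptive"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if strategy is None:
        strategy = "min_score" if protocol == "guided_adaptive" else "random"
    S_values = np.asarray(list(S_values), dtype=int)
    count_values = np.asarray(list(count_values), dtype=int)
    med = np.empty((len(S_values), len(count_values)))
    frac = np.empty_like(med)
    for i, S in enumerate(S_values):
        for j, count in enumerate(count_values):
            times = []
            for rep in range(replicates):
                cell_seed = int(np.random.default_rng(
                    [seed, i, j, rep]).integers(2 ** 31))
                sampler = sampler_factory()
                if protocol == "serial":
                    t = _serial_run(sampler, int(count), int(S), cell_seed)
                else:
                    R = max(1, int(count) // n_parallel)
                    cfg = AdaptiveRunConfig(
                        n_parallel=n_parallel, traj_length=int(S),
                        n_rounds=R, n_clusters=n_clusters, strategy=strategy,
                        seed=cell_seed, cluster_stride=cluster_stride)
                    t = adaptive_run(sampler, cfg).total_time
                times.append(t)
            med[i, j] = float(np.median(times))
            frac[i, j] = float(np.mean(np.isfinite(times)))
    return FPTGridResult(protocol=protocol, S_values=S_values,
                         count_values=count_values, median_total_time=med,
                         hit_fraction=frac, replicates=replicates)
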