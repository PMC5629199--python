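"""Kinetic Monte Carlo on a transition matrix.

Generates discrete-time state-to-state trajectories from a row-stochastic
T(tau).  Each step draws a uniform variate u in [0, 1) and walks the
cumulative sums S_n = sum_{j<=n} p_ij of the current row: the chain moves to
the state j whose cumulative interval [S_{j-1}, S_j) contains u.  This is
the discrete-time scheme; waiting-time (Gillespie) KMC on rate matrices is
out of scope.

First-passage summaries report hit times in units of the model lag time tau
(one KMC step = one tau).  Replicate streams are derived from (seed,
trajectory index) with ``numpy.random.default_rng`` sequence seeding, so an
ensemble is reproducible and independent of launch order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np

from .errors import DegenerateInputError, DomainError, MatrixError
from .msm import DiscreteTrajectory, TransitionMatrix

__all__ = ["KMCTrajectory", "FirstPassageSummary", "kmc_step", "kmc_ensemble"]


@dataclass
class KMCTrajectory:
    """One KMC realization; truncated at the first stop-set entry if any."""

    dtraj: DiscreteTrajectory
    seed: int
    start: int
    stop_set: Optional[frozenset] = None
    hit_index: Optional[int] = None  # first frame inside the stop set

    @property
    def states(self):
        return self.dtraj.states

    @property
    def hit_time(self) -> Optional[float]:
        """First-passage time in tau units, or None if the stop set was not hit."""
        if self.hit_index is None:
            return None
        return self.hit_index * self.dtraj.frame_interval


@dataclass
class FirstPassageSummary:
    """Ensemble first-passage statistics, in units of tau."""

    n_traj: int
    n_hit: int
    hit_fraction: float
    mean_hit_time: float  # NaN when nothing hit
    median_hit_time: float
    std_hit_time: float
    hit_times: np.ndarray


def _row_matrix(T) -> np.ndarray:
    M = T.matrix if isinstance(T, TransitionMatrix) else np.asarray(T, float)
    rows = M.sum(axis=1)
    if np.max(np.abs(rows - 1.0)) > 1e-9:
        raise MatrixError(
            f"row sums deviate from 1 by {np.max(np.abs(rows - 1.0)):.2e}")
    return M


def kmc_step(T, state: int, u: float) -> int:
    """One KMC transition by the cumulative-sum rule.

    Returns the state j with S_{j-1} <= u < S_j for the cumulative sums S of
    row ``state``.  u = 0 maps to the first state with positive probability.
    """
    M = _row_matrix(T)
    if not 0 <= state < M.shape[0]:
        raise DomainError(f"state {state} outside 0..{M.shape[0] - 1}")
    if not 0.0 <= u < 1.0:
        raise DomainError(f"u={u} outside [0, 1)")
    S = np.cumsum(M[state])
    return int(np.searchsorted(S, u, side="right"))


def _traj_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def kmc_ensemble(T, start: int, n_traj: int, n_steps: int,
                 stop_set: Optional[Iterable[int]] = None,
                 seed: int = 0, frame_interval: float = 1.0):
    """Run an ensemble of KMC trajectories and summarize first passage.

    Each trajectory starts at ``start`` and runs ``n_steps`` transitions,
    truncating at the first entry into ``stop_set`` (the truncated
    trajectory ends on the hitting frame).  Hit times count transitions,
    so hitting on the very next step is a hit time of 1 tau.

    Returns (list of KMCTrajectory, FirstPassageSummary).
    """
    M = _row_matrix(T)
    interval = T.tau if isinstance(T, TransitionMatrix) else frame_interval
    if n_traj < 1 or n_steps < 1:
        raise ValueError("n_traj and n_steps must be >= 1")
    stops = frozenset(int(s) for s in stop_set) if stop_set is not None else None
    if stops and start in stops:
        raise DegenerateInputError("start state lies inside the stop set")
    cum = np.cumsum(M, axis=1)
    trajs: List[KMCTrajectory] = []
    hit_times = []
    for itraj in range(n_traj):
        rng = _traj_rng(seed, itraj)
        u = rng.random(n_steps)
        states = np.empty(n_steps + 1, dtype=np.int64)
        states[0] = start
        s = start
        hit = None
        length = n_steps
        for t in range(n_steps):
            s = int(np.searchsorted(cum[s], u[t], side="right"))
            states[t + 1] = s
            if stops is not None and s in stops:
                hit = t + 1
                length = t + 1
                break
        dt = DiscreteTrajectory(states[:length + 1], interval)
        trajs.append(KMCTrajectory(dt, seed=seed, start=start,
                                   stop_set=stops, hit_index=hit))
        if hit is not None:
            hit_times.append(hit * interval)
    ht = np.asarray(hit_times, dtype=float)
    summary = FirstPassageSummary(
        n_traj=n_traj,
        n_hit=len(ht),
        hit_fraction=len(ht) / n_traj,
        mean_hit_time=float(ht.mean()) if len(ht) else float("nan"),
        median_hit_time=float(np.median(ht)) if len(ht) else float("nan"),
        std_hit_time=float(ht.std(ddof=1)) if len(ht) > 1 else float("nan"),
        hit_times=ht,
    )
    return trajs, summary


def empirical_transition_matrix(trajs: Iterable[KMCTrajectory],
                                n_states: int) -> np.ndarray:
    """Row-normalized transition frequencies observed in KMC trajectories."""
    C = np.zeros((n_states, n_states))
    for tr in trajs:
        s = tr.states
        np.add.at(C, (s[:-1], s[1:]), 1.0)
    rows = C.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return C / rows


def analytic_mfpt(T, target_set: Iterable[int]) -> np.ndarray:
    """Mean first-passage times to a target set via the fundamental matrix.

    For the substochastic block Q over non-target states, the MFPT vector is
    (I - Q)^{-1} 1, in units of steps (tau).  Used as the closed-form
    cross-check for KMC first-passage estimates.
    """
    M = T.matrix if isinstance(T, TransitionMatrix) else np.asarray(T, float)
    n = M.shape[0]
    targets = sorted(set(int(t) for t in target_set))
    others = [i for i in range(n) if i not in targets]
    Q = M[np.ix_(others, others)]
    t = np.linalg.solve(np.eye(len(others)) - Q, np.ones(len(others)))
    out = np.zeros(n)
    out[others] = t
    return out
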