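"""Markov state models: clustering, counting, reversible estimation, tICA.

A Markov state model (MSM) represents dynamics as a Markov chain on a
discretization of conformational space.  Transitions observed at a lag time
tau are counted with a sliding window, counts are trimmed to their largest
strongly connected component, and a transition matrix T(tau) is estimated by
maximum likelihood under the detailed-balance constraint
pi_i T_ij = pi_j T_ji.  Probability mass then propagates as

    p(t0 + k tau) = p(t0) T(tau)^k

and the relaxation timescale of each non-stationary eigenvalue lambda is
t = -tau / ln(lambda); MSM validity is judged by convergence of these
implied timescales in the lag time.

The reversible maximum-likelihood estimator is the standard self-consistent
fixed point: with c_i the row sums of the count matrix C and x_ij the
(symmetric) estimated equilibrium flux,

    x_ij <- (C_ij + C_ji) / (c_i / x_i + c_j / x_j),

iterated to convergence; then T_ij = x_ij / x_i and pi_i = x_i / sum(x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sparse
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .errors import (CardinalityError, ConnectivityError, EstimationError,
                     LagError, MatrixError)
from .structio import FeatureTrajectory

__all__ = [
    "DiscreteTrajectory",
    "CountMatrix",
    "TransitionMatrix",
    "MSModel",
    "cluster_kmeans",
    "count_and_trim",
    "estimate_reversible",
    "stationary_distribution",
    "implied_timescales",
    "tica_project",
    "propagate",
]

ROW_SUM_TOL = 1e-12
REVERSIBLE_TOL = 1e-10
REVERSIBLE_MAX_ITER = 1_000_000


@dataclass
class DiscreteTrajectory:
    """A sequence of 0-based state labels at a fixed frame interval."""

    states: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError("state sequence must be a non-empty 1-D array")
        if self.states.min() < 0:
            raise ValueError("state labels must be non-negative")

    def __len__(self):
        return self.states.size


@dataclass
class CountMatrix:
    """Transition counts at a lag, over the active (connected) state set."""

    counts: np.ndarray
    lag: int
    active_set: np.ndarray  # original labels of the rows/columns
    counting_mode: str = "sliding"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.active_set = np.asarray(self.active_set, dtype=np.int64)
        if self.counts.min() < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class TransitionMatrix:
    """Row-stochastic T(tau) with a map back to original state labels."""

    matrix: np.ndarray
    lag: int = 1
    frame_interval: float = 1.0
    active_set: Optional[np.ndarray] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise MatrixError("transition matrix must be square")
        if self.active_set is None:
            self.active_set = np.arange(n)
        rows = self.matrix.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-9:
            raise MatrixError(
                f"rows must sum to 1 (max deviation {np.max(np.abs(rows - 1.0)):.2e})")
        if self.matrix.min() < -ROW_SUM_TOL or self.matrix.max() > 1 + 1e-9:
            raise MatrixError("entries must lie in [0, 1]")
        # renormalize away float dust so downstream cumulative sums end at 1
        self.matrix = np.clip(self.matrix, 0.0, None)
        self.matrix /= self.matrix.sum(axis=1, keepdims=True)

    @property
    def n_states(self):
        return self.matrix.shape[0]

    @property
    def tau(self):
        return self.lag * self.frame_interval


@dataclass
class MSModel:
    """A transition matrix with its stationary distribution and timescales."""

    tmatrix: TransitionMatrix
    pi: np.ndarray
    timescales: np.ndarray = field(default=None)

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("stationary distribution must sum to 1")
        if self.timescales is None:
            self.timescales = implied_timescales_from_matrix(self.tmatrix)

    @property
    def T(self):
        return self.tmatrix.matrix


def propagate(p0: np.ndarray, T: np.ndarray, k: int) -> np.ndarray:
    """Propagate a row probability vector k lag steps: p(t0) T^k.

    Applied stepwise (k successive vector-matrix products), which is both
    cheaper than forming the matrix power and bitwise-reproducible against
    a stepwise reference.
    """
    p = np.asarray(p0, dtype=float)
    M = np.asarray(T.matrix if isinstance(T, TransitionMatrix) else T, float)
    for _ in range(k):
        p = p @ M
    return p


def cluster_kmeans(features, k: int, seed: int = 0,
                   frame_interval: float = 1.0):
    """k-means microstate clustering (k-means++ init, deterministic per seed).

    ``features`` is one frames x d matrix or a list of them; returns one
    DiscreteTrajectory per input plus the (k, d) cluster centers.
    """
    single = False
    if isinstance(features, FeatureTrajectory):
        features = [features]
    if isinstance(features, np.ndarray) and features.ndim == 2:
        features = [features]
        single = True
    mats = [f.values if isinstance(f, FeatureTrajectory) else np.asarray(f, float)
            for f in features]
    X = np.vstack(mats)
    if k > X.shape[0]:
        raise CardinalityError(f"k={k} exceeds {X.shape[0]} frames")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    # nearest-center assignment (argmin ties resolve to the lowest index)
    labels = km.predict(X)
    out, start = [], 0
    for m in mats:
        out.append(DiscreteTrajectory(labels[start:start + len(m)], frame_interval))
        start += len(m)
    return (out[0] if single else out), km.cluster_centers_


def _as_dtrajs(dtrajs) -> List[DiscreteTrajectory]:
    if isinstance(dtrajs, DiscreteTrajectory):
        return [dtrajs]
    return [d if isinstance(d, DiscreteTrajectory) else DiscreteTrajectory(d)
            for d in dtrajs]


def count_and_trim(dtrajs, lag: int):
    """Sliding-window transition counts, restricted to the largest SCC.

    Every frame t with t + lag inside the trajectory contributes one count
    C[s_t, s_{t+lag}].  The active set is the largest strongly connected
    component of the directed count graph (ties broken toward the component
    containing the lowest state label); counts are restricted to it.
    """
    trajs = _as_dtrajs(dtrajs)
    if lag < 1:
        raise LagError("lag must be >= 1")
    if lag >= max(len(t) for t in trajs):
        raise LagError(
            f"lag {lag} is not shorter than the longest trajectory "
            f"({max(len(t) for t in trajs)} frames)")
    n = int(max(t.states.max() for t in trajs)) + 1
    C = np.zeros((n, n))
    for t in trajs:
        s = t.states
        if len(s) <= lag:
            continue
        np.add.at(C, (s[:-lag], s[lag:]), 1.0)
    graph = sparse.csr_matrix(C > 0)
    n_comp, assign = connected_components(graph, directed=True, connection="strong")
    sizes = np.bincount(assign, minlength=n_comp)
    # visit-weight tie-break: prefer the component with more total counts
    weights = np.zeros(n_comp)
    np.add.at(weights, assign, C.sum(axis=1) + C.sum(axis=0))
    best = max(range(n_comp), key=lambda c: (sizes[c], weights[c], -c))
    active = np.flatnonzero(assign == best)
    return CountMatrix(C[np.ix_(active, active)], lag, active), active


def estimate_reversible(C: CountMatrix, tol: float = REVERSIBLE_TOL,
                        max_iter: int = REVERSIBLE_MAX_ITER,
                        frame_interval: float = 1.0) -> MSModel:
    """Reversible maximum-likelihood transition matrix from counts.

    Maximizes the multinomial likelihood prod T_ij^{C_ij} subject to
    detailed balance, by the self-consistent fixed-point iteration on the
    symmetric flux matrix x_ij (see module docstring).  The stationary
    distribution comes from the converged flux row sums.
    """
    Cm = np.asarray(C.counts, float)
    n = Cm.shape[0]
    rows = Cm.sum(axis=1)
    if np.any(rows == 0):
        raise ConnectivityError("count matrix has an all-zero row; trim first")
    ncomp, _ = connected_components(sparse.csr_matrix(Cm > 0), directed=True,
                                    connection="strong")
    if ncomp != 1:
        raise ConnectivityError(
            "count matrix is not strongly connected; run count_and_trim")
    Csym = Cm + Cm.T
    X = Csym / Csym.sum()
    resid = np.inf
    for _ in range(max_iter):
        x = X.sum(axis=1)
        denom = rows[:, None] / x[:, None] + rows[None, :] / x[None, :]
        X_new = np.where(Csym > 0, Csym / denom, 0.0)
        X_new /= X_new.sum()
        resid = np.max(np.abs(X_new - X))
        X = X_new
        if resid < tol:
            break
    else:
        raise EstimationError(
            f"reversible MLE did not converge (residual {resid:.2e})")
    x = X.sum(axis=1)
    T = X / x[:, None]
    T /= T.sum(axis=1, keepdims=True)
    tm = TransitionMatrix(T, lag=C.lag, frame_interval=frame_interval,
                          active_set=C.active_set)
    return MSModel(tm, pi=x / x.sum())


def stationary_distribution(T: TransitionMatrix) -> np.ndarray:
    """Stationary distribution: the left eigenvector for eigenvalue 1."""
    M = T.matrix if isinstance(T, TransitionMatrix) else np.asarray(T, float)
    ncomp, _ = connected_components(sparse.csr_matrix(M > 0), directed=True,
                                    connection="strong")
    if ncomp != 1:
        raise ConnectivityError("transition matrix is reducible")
    vals, vecs = scipy.linalg.eig(M, left=True, right=False)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _eigenvalues_reversible(T: TransitionMatrix, pi: np.ndarray) -> np.ndarray:
    """Eigenvalues via the pi-symmetrized form (real for reversible T)."""
    s = np.sqrt(pi)
    sym = (s[:, None] / s[None, :]) * T.matrix
    sym = 0.5 * (sym + sym.T)
    return np.sort(scipy.linalg.eigvalsh(sym))[::-1]


def implied_timescales_from_matrix(T: TransitionMatrix,
                                   pi: Optional[np.ndarray] = None) -> np.ndarray:
    """t_i = -tau / ln(lambda_i), stationary eigenvalue excluded.

    Eigenvalues <= 0 have no relaxation interpretation and are reported as
    NaN for that process.
    """
    if pi is None:
        pi = stationary_distribution(T)
    lam = _eigenvalues_reversible(T, pi)[1:]
    out = np.full(lam.shape, np.nan)
    pos = lam > 0
    out[pos] = -T.tau / np.log(lam[pos])
    return out


def implied_timescales(dtrajs, lags: Sequence[int],
                       frame_interval: float = 1.0) -> dict:
    """Implied timescales of the reversible estimate at each lag."""
    out = {}
    for lag in lags:
        C, _ = count_and_trim(dtrajs, lag)
        model = estimate_reversible(C, frame_interval=frame_interval)
        out[lag] = implied_timescales_from_matrix(model.tmatrix, model.pi)
    return out


def tica_project(features, lag: int, n_components: int,
                 reg: float = 1e-10) -> FeatureTrajectory:
    """Time-lagged independent component analysis projection.

    Solves the generalized eigenproblem C_tau v = lambda C_0 v with the
    symmetrized time-lagged covariance C_tau and the instantaneous
    covariance C_0 (regularized by reg * trace/d on its diagonal), and
    projects the mean-free data onto the top ``n_components`` eigenvectors
    (the slowest linear collective coordinates).
    """
    if isinstance(features, FeatureTrajectory):
        interval = features.frame_interval
        X = features.values
    else:
        interval = 1.0
        X = np.asarray(features, float)
    nf, d = X.shape
    if lag >= nf:
        raise LagError(f"lag {lag} >= number of frames {nf}")
    if n_components > d:
        raise ValueError("n_components exceeds feature dimension")
    mean = X.mean(axis=0)
    Y = X - mean
    A, B = Y[:-lag], Y[lag:]
    m = nf - lag
    C0 = (A.T @ A + B.T @ B) / (2 * m)
    Ct = (A.T @ B + B.T @ A) / (2 * m)
    C0 = C0 + np.eye(d) * (reg * np.trace(C0) / d)
    try:
        vals, vecs = scipy.linalg.eigh(Ct, C0)
    except scipy.linalg.LinAlgError as exc:
        raise EstimationError(f"singular covariance after regularization: {exc}")
    order = np.argsort(vals)[::-1][:n_components]
    proj = Y @ vecs[:, order]
    labels = tuple(f"tic_{i + 1}" for i in range(n_components))
    return FeatureTrajectory(proj, labels, interval)
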