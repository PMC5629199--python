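"""Transition path theory on a Markov state model.

Given a source set A and sink set B, the forward committor q+ is the
probability of reaching B before A from each state; the backward committor
q- is its analogue on the time-reversed chain.  Reactive probability
current flows along

    f_ij = pi_i q-_i T_ij q+_j          (i != j)

and the net flux F_ij = max(0, f_ij - f_ji) carries the A -> B transition.
Top pathways are extracted iteratively: find the maximum-bottleneck
(widest) A -> B path by a Dijkstra variant with max-min relaxation, record
its bottleneck flux, subtract it along the path, and repeat.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ConnectivityError
from .msm import MSModel

__all__ = ["FluxNetwork", "committors", "net_flux", "top_pathways"]

RESIDUAL_FLUX_TOL = 1e-12


@dataclass
class FluxNetwork:
    """Committors and fluxes between a source set A and sink set B."""

    q_minus: np.ndarray
    q_plus: np.ndarray
    gross_flux: np.ndarray
    net: np.ndarray
    source: tuple
    sink: tuple

    @property
    def total_flux(self) -> float:
        """Total reactive A -> B flux (out of A, equal to flux into B)."""
        return float(self.net[list(self.source)].sum())


def _check_sets(n, A, B):
    A = sorted(set(int(a) for a in A))
    B = sorted(set(int(b) for b in B))
    if not A or not B:
        raise ValueError("source and sink sets must be non-empty")
    if set(A) & set(B):
        raise ValueError("source and sink sets must be disjoint")
    if min(A + B) < 0 or max(A + B) >= n:
        raise ValueError("source/sink state outside the active set")
    return A, B


def committors(m: MSModel, A: Sequence[int], B: Sequence[int]):
    """Forward and backward committors by direct linear solve.

    q+ solves sum_j T_ij q+_j = q+_i on intermediate states with boundary
    values 0 on A and 1 on B; q- solves the same system on the reversed
    chain T~_ij = (pi_j / pi_i) T_ji with the roles of A and B swapped.
    Returns (q_minus, q_plus).
    """
    T = m.T
    n = T.shape[0]
    A, B = _check_sets(n, A, B)

    def solve_forward(M, src, snk):
        q = np.zeros(n)
        q[snk] = 1.0
        inter = [i for i in range(n) if i not in src and i not in snk]
        if inter:
            K = M[np.ix_(inter, inter)] - np.eye(len(inter))
            rhs = -M[np.ix_(inter, snk)].sum(axis=1)
            try:
                q[inter] = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError as exc:
                raise ConnectivityError(
                    f"committor system singular (disconnected states?): {exc}")
        return np.clip(q, 0.0, 1.0)

    pi = m.pi
    Trev = (pi[None, :] / pi[:, None]) * T.T
    q_plus = solve_forward(T, A, B)
    q_minus = solve_forward(Trev, B, A)
    return q_minus, q_plus


def net_flux(m: MSModel, q_minus: np.ndarray, q_plus: np.ndarray,
             A: Sequence[int], B: Sequence[int]) -> FluxNetwork:
    """Gross and net reactive flux matrices from the committors."""
    T = m.T
    n = T.shape[0]
    A, B = _check_sets(n, A, B)
    f = (m.pi * q_minus)[:, None] * T * q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    F = np.clip(f - f.T, 0.0, None)
    return FluxNetwork(q_minus=q_minus, q_plus=q_plus, gross_flux=f, net=F,
                       source=tuple(A), sink=tuple(B))


def _widest_path(F: np.ndarray, sources, sinks) -> Tuple[list, float]:
    """Maximum-bottleneck path by Dijkstra with max-min relaxation.

    Ties between equal-bottleneck routes break toward fewer hops, then
    lexicographically smaller state sequences, so extraction is
    deterministic.  Returns ([], 0.0) when no path exists.
    """
    n = F.shape[0]
    # width, hops, prev; priority queue keyed by (-width, hops, state)
    width = np.full(n, -1.0)
    hops = np.full(n, np.inf)
    prev = np.full(n, -1, dtype=int)
    heap = []
    for s in sources:
        width[s] = np.inf
        hops[s] = 0
        heapq.heappush(heap, (-np.inf, 0, s))
    sink_set = set(sinks)
    visited = np.zeros(n, bool)
    while heap:
        negw, h, u = heapq.heappop(heap)
        w = -negw
        if visited[u] or w < width[u]:
            continue
        visited[u] = True
        if u in sink_set:
            path = [u]
            while prev[path[-1]] != -1:
                path.append(prev[path[-1]])
            return path[::-1], float(w)
        for v in np.flatnonzero(F[u] > 0):
            if visited[v]:
                continue
            cand = min(w, F[u, v])
            better = (cand > width[v] or
                      (cand == width[v] and h + 1 < hops[v]) or
                      (cand == width[v] and h + 1 == hops[v] and u < prev[v]))
            if better:
                width[v] = cand
                hops[v] = h + 1
                prev[v] = u
                heapq.heappush(heap, (-cand, h + 1, v))
    return [], 0.0


def top_pathways(fn: FluxNetwork, k: int) -> List[Tuple[list, float]]:
    """The k highest-flux A -> B pathways by iterative bottleneck removal.

    Each iteration finds the widest path through the residual net-flux
    network, reports (path, bottleneck flux), and subtracts the bottleneck
    along the path.  Stops early once residual connectivity or flux falls
    below 1e-12; returns an empty list if A and B are not connected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    F = fn.net.copy()
    out = []
    for _ in range(k):
        path, w = _widest_path(F, fn.source, fn.sink)
        if not path or w < RESIDUAL_FLUX_TOL:
            break
        for a, b in zip(path[:-1], path[1:]):
            F[a, b] -= w
        out.append((path, w))
    return out
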