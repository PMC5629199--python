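"""Synthetic known-answer systems for testing and benchmarking.

Three generator families make the whole toolkit testable without external
simulation data:

* :func:`generate_msm` -- a 1-D nearest-neighbor Metropolis chain on a
  double-well energy profile ("funnel" toward a target state).  Its
  stationary distribution equals the Boltzmann weights of the profile in
  closed form, and a scalar per-state coordinate (distance to the target)
  stands in for the dSEC guidance score.
* :func:`generate_guided_landscape` -- the same chain bundled with a noisy
  guidance score whose anti-correlation with the forward committor is
  guaranteed by construction: informative but imperfect guidance.
* :func:`generate_toy_complex` -- two rigid toy chains whose native pose
  minimizes the sum of coupled-pair distances, plus rigid-displacement
  decoys and the matching inter-chain coupling table, written in the same
  formats the real pipeline consumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from typing import Optional

import numpy as np
from scipy.stats import spearmanr

from .couplings import CouplingRecord, CouplingSet
from .msm import MSModel, TransitionMatrix
from .structio import Atom, Structure
from .tpt import committors

__all__ = [
    "FunnelChainSpec",
    "GuidedLandscape",
    "ToyComplex",
    "generate_msm",
    "generate_guided_landscape",
    "generate_toy_complex",
    "write_transition_matrix",
    "write_structure_pdb",
]


@dataclass(frozen=True)
class FunnelChainSpec:
    """Parameters of the 1-D double-well Metropolis chain.

    The energy profile has a well at the start state and a deeper well at
    the target state, separated by a barrier of the given height (in kT
    units, i.e. log-probability penalty).  seed controls the mild
    deterministic ruggedness added to the profile.
    """

    n_states: int = 50
    barrier: float = 6.0
    start: int = 0
    target: Optional[int] = None
    seed: int = 0
    ruggedness: float = 0.5

    def __post_init__(self):
        if self.n_states < 3:
            raise ValueError("need at least 3 states")
        tgt = self.n_states - 1 if self.target is None else self.target
        object.__setattr__(self, "target", tgt)
        if not (0 <= self.start < self.n_states) or not (0 <= tgt < self.n_states):
            raise ValueError("start/target outside the chain")
        if self.start == tgt:
            raise ValueError("start and target must differ")


def _energy_profile(spec: FunnelChainSpec) -> np.ndarray:
    """Double-well profile: wells at start and (deeper) target, barrier between."""
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(0.0, 1.0, spec.n_states)
    xs = x[spec.start]
    xt = x[spec.target]
    mid = 0.5 * (xs + xt)
    halfspan = max(abs(xt - xs) / 2, 1e-6)
    # inverted parabola peaking at the midpoint between the wells
    E = spec.barrier * (1.0 - ((x - mid) / halfspan) ** 2)
    E = np.clip(E, a_min=None, a_max=spec.barrier)
    E += rng.uniform(0.0, spec.ruggedness, size=spec.n_states)
    E[spec.start] = 0.0
    E[spec.target] = -2.0  # target well deeper than start: funnel
    return E


def generate_msm(spec: FunnelChainSpec):
    """Metropolis nearest-neighbor chain with exactly known equilibrium.

    Proposals move to each neighbor with probability 1/2 and are accepted
    with min(1, exp(-(E_j - E_i))); the diagonal absorbs the rest.  The
    construction satisfies detailed balance with pi proportional to
    exp(-E), so the stationary distribution is known in closed form.

    Returns (MSModel, coordinate) where coordinate[i] = |i - target| /
    (n - 1) is the distance-to-target proxy for the dSEC guidance score
    (strictly decreasing toward the target state).
    """
    E = _energy_profile(spec)
    n = spec.n_states
    T = np.zeros((n, n))
    for i in range(n):
        for j in (i - 1, i + 1):
            if 0 <= j < n:
                T[i, j] = 0.5 * min(1.0, np.exp(-(E[j] - E[i])))
        T[i, i] = 1.0 - T[i].sum()
    pi = np.exp(-E)
    pi /= pi.sum()
    model = MSModel(TransitionMatrix(T, lag=1), pi=pi)
    coord = np.abs(np.arange(n) - spec.target) / (n - 1)
    return model, coord


@dataclass
class GuidedLandscape:
    """A funnel MSM plus a noisy dSEC-like guidance score and target set."""

    model: MSModel
    score: np.ndarray
    target: tuple
    start: int
    coordinate: np.ndarray
    spearman_score_committor: float


def generate_guided_landscape(n_states: int = 50, seed: int = 0,
                              noise: float = 0.05,
                              barrier: float = 6.0) -> GuidedLandscape:
    """Funnel chain with guidance that anti-correlates with the committor.

    The score is the distance-to-target coordinate plus seeded Gaussian
    noise, regenerated (up to 100 attempts at decreasing noise) until its
    Spearman correlation with the forward committor is <= -0.8, so the
    guidance is informative but imperfect.  Deterministic per seed.
    """
    if n_states < 10:
        raise ValueError("need at least 10 states")
    spec = FunnelChainSpec(n_states=n_states, barrier=barrier, seed=seed)
    model, coord = generate_msm(spec)
    _, q_plus = committors(model, [spec.start], [spec.target])
    rng = np.random.default_rng([seed, 1])
    level = noise
    for _ in range(100):
        score = coord + rng.normal(0.0, level, size=n_states)
        rho = spearmanr(score, q_plus).statistic
        if rho <= -0.8:
            break
        level *= 0.5
    return GuidedLandscape(model=model, score=score, target=(spec.target,),
                           start=spec.start, coordinate=coord,
                           spearman_score_committor=float(rho))


@dataclass
class ToyComplex:
    """Native two-chain pose, decoys, and the matching coupling table."""

    native: Structure
    decoys: list
    couplings: CouplingSet


def _chain_atoms(chain_id: str, coords: np.ndarray, resname: str = "GLY"):
    return [Atom(name="CA", resname=resname, resseq=i + 1, chain=chain_id,
                 icode="", occupancy=1.0, xyz=tuple(map(float, c)))
            for i, c in enumerate(coords)]


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def generate_toy_complex(n_residues_per_chain: int = 6, n_decoys: int = 10,
                         seed: int = 0) -> ToyComplex:
    """Two rigid toy chains whose native pose minimizes SEC.

    Chain A is a straight Calpha trace along x; chain B lies parallel at
    4 A separation in the native pose.  The coupling table lists the
    residue-aligned inter-chain contacts of the native pose with scores
    descending along the interface.  Decoys rigidly rotate and displace
    chain B (displacements of at least 5 A), so every decoy's summed
    coupled-pair distance exceeds the native one.
    """
    if n_residues_per_chain < 3:
        raise ValueError("need at least 3 residues per chain")
    rng = np.random.default_rng(seed)
    n = n_residues_per_chain
    a_coords = np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
    b_native = a_coords + np.array([0.0, 4.0, 0.0])
    native = Structure(tuple(_chain_atoms("A", a_coords) +
                             _chain_atoms("B", b_native)))
    records = [CouplingRecord(residue_i=i + 1, residue_j=i + 1,
                              score=round(1.0 - 0.05 * i, 4),
                              chain_i="A", chain_j="B") for i in range(n)]
    couplings = CouplingSet(tuple(records), selection="all", source="toy_complex")
    native_sec = float(np.linalg.norm(a_coords - b_native, axis=1).sum())
    decoys = []
    while len(decoys) < n_decoys:
        R = _random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = direction * rng.uniform(5.0, 60.0)
        center = b_native.mean(axis=0)
        b_dec = (b_native - center) @ R.T + center + shift
        # emit only poses that keep the native SEC strictly minimal
        if np.linalg.norm(a_coords - b_dec, axis=1).sum() <= native_sec:
            continue
        decoys.append(Structure(tuple(_chain_atoms("A", a_coords) +
                                      _chain_atoms("B", b_dec))))
    return ToyComplex(native=native, decoys=decoys, couplings=couplings)


def write_transition_matrix(T: np.ndarray, path) -> None:
    """Write a transition matrix as plain CSV (one row per line)."""
    np.savetxt(path, np.asarray(T, float), delimiter=",")


def write_structure_pdb(s: Structure, path) -> None:
    """Write a Structure as minimal PDB ATOM records (file-order preserving)."""
    with open(path, "w") as fh:
        for i, a in enumerate(s.atoms, start=1):
            x, y, z = a.xyz
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {i:5d} {name}{'':1s}{a.resname:>3s} {a.chain:1s}"
                f"{a.resseq:4d}{a.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.name[0]:>2s}\n")
        fh.write("END\n")


def write_coupling_csv(cs: CouplingSet, path, dialect: str = "complex") -> None:
    """Write a CouplingSet in the CSV dialects read_coupling_table accepts."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if dialect == "complex":
            w.writerow(["chain_i", "i", "chain_j", "j", "score"])
            for r in cs:
                w.writerow([r.chain_i, r.residue_i, r.chain_j, r.residue_j,
                            r.score])
        else:
            w.writerow(["i", "j", "score"])
            for r in cs:
                w.writerow([r.residue_i, r.residue_j, r.score])
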