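"""Overdamped 2-D Brownian dynamics on a rugged Gaussian-well potential.

The benchmark system for adaptive-sampling strategy comparisons: a particle
diffusing on a configurable surface built from Gaussian wells

    U(x) = sum_k -A_k exp(-|x - c_k|^2 / (2 w_k^2)) + (kappa/2) |x - c0|^2

integrated with the Euler-Maruyama scheme for the overdamped Langevin
equation,

    x_{t+1} = x_t - (D dt / kT) grad U(x_t) + sqrt(2 D dt) xi_t,

with xi_t a standard 2-D normal.  The shipped default surface is a funnel:
a deep start well in the top-right corner, a deep target well at the
origin, and a deterministic pseudo-random field of shallow wells in
between, under quadratic confinement.  Serial trajectories rarely escape
the start well on the benchmark protocol's timescale, while
distance-guided adaptive reseeding ratchets across the intervening
barriers -- the qualitative ordering the strategy comparison measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .errors import InstabilityError

__all__ = [
    "GaussianWell",
    "Potential2D",
    "BrownianParams",
    "potential_eval",
    "simulate",
    "simulate_batch",
    "default_potential",
    "default_params",
    "load_potential",
    "save_potential",
]


@dataclass(frozen=True)
class GaussianWell:
    center: tuple  # (x, y)
    depth: float   # well depth in kT units (> 0 means attractive)
    width: float   # Gaussian sigma, length units

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("well width must be positive")


@dataclass(frozen=True)
class Potential2D:
    """Gaussian wells plus optional quadratic confinement, with start/target.

    ``channel_stiffness`` adds a quadratic penalty on the perpendicular
    distance from the line through the start and target well centers,
    confining dynamics to a corridor so that the rugged path between the
    two deep wells cannot be bypassed through flat terrain.
    """

    wells: tuple
    confinement_center: Optional[tuple] = None
    confinement_stiffness: float = 0.0
    channel_stiffness: float = 0.0
    start_well: int = 0
    target_well: int = 1

    def __post_init__(self):
        if not self.wells:
            raise ValueError("potential needs at least one well")
        if self.start_well == self.target_well and len(self.wells) > 1:
            raise ValueError("target well must differ from start well")

    @property
    def start(self) -> np.ndarray:
        return np.asarray(self.wells[self.start_well].center, float)

    @property
    def target(self) -> np.ndarray:
        return np.asarray(self.wells[self.target_well].center, float)

    def domain_scale(self) -> float:
        centers = np.array([w.center for w in self.wells], float)
        return max(1.0, float(np.abs(centers).max()))


@dataclass(frozen=True)
class BrownianParams:
    """Integrator parameters.

    diffusion D in length^2/time, timestep dt in time, thermal energy kT in
    the same units as well depths, n_steps transitions per trajectory.
    """

    diffusion: float = 1.0
    dt: float = 2e-4
    kT: float = 1.0
    n_steps: int = 300_000
    seed: int = 0

    def __post_init__(self):
        if min(self.diffusion, self.dt, self.kT) <= 0 and self.diffusion != 0:
            raise ValueError("dt and kT must be positive, D non-negative")
        if self.diffusion < 0:
            raise ValueError("diffusion must be non-negative")


_ARRAY_CACHE: dict = {}


def _well_arrays(p: Potential2D):
    key = id(p)
    hit = _ARRAY_CACHE.get(key)
    if hit is None or hit[0] is not p:
        centers = np.array([w.center for w in p.wells], float)
        depths = np.array([w.depth for w in p.wells], float)
        widths = np.array([w.width for w in p.wells], float)
        if len(_ARRAY_CACHE) > 64:
            _ARRAY_CACHE.clear()
        _ARRAY_CACHE[key] = hit = (p, centers, depths, widths)
    return hit[1], hit[2], hit[3]


def _gradient(p: Potential2D, pts: np.ndarray) -> np.ndarray:
    """Gradient only, for the integrator's inner loop; pts is (n, 2)."""
    centers, depths, widths = _well_arrays(p)
    diff = pts[:, None, :] - centers[None, :, :]
    r2 = np.einsum("nkd,nkd->nk", diff, diff)
    g = np.exp(r2 * (-0.5 / widths[None, :] ** 2))
    coef = (depths / widths ** 2)[None, :] * g
    grad = np.einsum("nk,nkd->nd", coef, diff)
    if p.confinement_stiffness:
        c0 = np.asarray(p.confinement_center or (0.0, 0.0), float)
        grad = grad + p.confinement_stiffness * (pts - c0)
    if p.channel_stiffness:
        axis = p.target - p.start
        axis = axis / np.linalg.norm(axis)
        normal = np.array([-axis[1], axis[0]])
        dperp = (pts - p.start) @ normal
        grad = grad + p.channel_stiffness * dperp[:, None] * normal[None, :]
    return grad


def potential_eval(p: Potential2D, x) -> tuple:
    """Energy and analytic gradient at one point or a batch of points.

    Accepts shape (2,) or (n, 2); returns (energy, gradient) with matching
    leading shape.
    """
    x = np.asarray(x, float)
    single = x.ndim == 1
    pts = x[None, :] if single else x
    centers, depths, widths = _well_arrays(p)
    diff = pts[:, None, :] - centers[None, :, :]        # (n, k, 2)
    r2 = np.sum(diff ** 2, axis=-1)                     # (n, k)
    g = np.exp(-r2 / (2 * widths[None, :] ** 2))
    energy = -(depths[None, :] * g).sum(axis=1)
    # d/dx of -A exp(-r^2 / 2w^2) = (A / w^2) exp(...) (x - c)
    coef = (depths / widths ** 2)[None, :] * g
    grad = (coef[:, :, None] * diff).sum(axis=1)
    if p.confinement_stiffness:
        c0 = np.asarray(p.confinement_center or (0.0, 0.0), float)
        d0 = pts - c0
        energy = energy + 0.5 * p.confinement_stiffness * np.sum(d0 ** 2, axis=1)
        grad = grad + p.confinement_stiffness * d0
    if p.channel_stiffness:
        axis = p.target - p.start
        axis = axis / np.linalg.norm(axis)
        normal = np.array([-axis[1], axis[0]])
        dperp = (pts - p.start) @ normal
        energy = energy + 0.5 * p.channel_stiffness * dperp ** 2
        grad = grad + p.channel_stiffness * dperp[:, None] * normal[None, :]
    if single:
        return float(energy[0]), grad[0]
    return energy, grad


try:  # JIT inner loop; a pure-numpy path covers environments without numba
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _em_kernel(x0, noise, centers, inv2w2, coefw, conf_c, conf_k,
               chan_k, p0, normal, mob, sigma, guard):
    n, steps = noise.shape[0], noise.shape[1]
    out = np.empty((n, steps + 1, 2))
    for i in range(n):
        x, y = x0[i, 0], x0[i, 1]
        out[i, 0, 0] = x
        out[i, 0, 1] = y
        for t in range(steps):
            gx = 0.0
            gy = 0.0
            for k in range(centers.shape[0]):
                dx = x - centers[k, 0]
                dy = y - centers[k, 1]
                e = np.exp(-(dx * dx + dy * dy) * inv2w2[k])
                c = coefw[k] * e
                gx += c * dx
                gy += c * dy
            gx += conf_k * (x - conf_c[0])
            gy += conf_k * (y - conf_c[1])
            dp = (x - p0[0]) * normal[0] + (y - p0[1]) * normal[1]
            gx += chan_k * dp * normal[0]
            gy += chan_k * dp * normal[1]
            x = x - mob * gx + sigma * noise[i, t, 0]
            y = y - mob * gy + sigma * noise[i, t, 1]
            out[i, t + 1, 0] = x
            out[i, t + 1, 1] = y
            if abs(x) > guard or abs(y) > guard:
                return out, i, t + 1
    return out, -1, -1


if _njit is not None:
    _em_kernel_jit = _njit(cache=True)(_em_kernel)
else:  # pragma: no cover
    _em_kernel_jit = _em_kernel


def _integrate(p: Potential2D, bp: BrownianParams, x0: np.ndarray,
               noise: np.ndarray) -> np.ndarray:
    """Euler-Maruyama integration given a pre-drawn noise block."""
    centers, depths, widths = _well_arrays(p)
    inv2w2 = 0.5 / widths ** 2
    coefw = depths / widths ** 2
    conf_c = np.asarray(p.confinement_center or (0.0, 0.0), float)
    if p.channel_stiffness:
        axis = p.target - p.start
        axis = axis / np.linalg.norm(axis)
        normal = np.array([-axis[1], axis[0]])
    else:
        normal = np.zeros(2)
    mob = bp.diffusion * bp.dt / bp.kT
    sigma = np.sqrt(2.0 * bp.diffusion * bp.dt)
    guard = 1e3 * p.domain_scale()
    out, bad_i, bad_t = _em_kernel_jit(
        np.ascontiguousarray(x0, dtype=float), noise, centers, inv2w2, coefw,
        conf_c, float(p.confinement_stiffness), float(p.channel_stiffness),
        p.start, normal, mob, sigma, guard)
    if bad_i >= 0:
        raise InstabilityError(
            f"trajectory {bad_i} diverged at step {bad_t} "
            f"(|x| > {guard:g}); reduce dt")
    return out


def simulate_batch(p: Potential2D, bp: BrownianParams, x0: np.ndarray,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Integrate a batch of trajectories with independent noise streams.

    x0 has shape (n, 2); returns (n, n_steps + 1, 2).  Noise is drawn as
    one block per trajectory from ``rng``.  Positions beyond 1000 x the
    domain scale raise InstabilityError (reduce dt).
    """
    if rng is None:
        rng = np.random.default_rng(bp.seed)
    x0 = np.atleast_2d(np.asarray(x0, float))
    n = x0.shape[0]
    noise = rng.standard_normal((n, bp.n_steps, 2))
    return _integrate(p, bp, x0, noise)


def simulate(p: Potential2D, bp: BrownianParams, x0,
             rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One Euler-Maruyama trajectory from x0; shape (n_steps + 1, 2)."""
    return simulate_batch(p, bp, np.asarray(x0, float)[None, :], rng)[0]


def default_potential(seed: int = 20170) -> Potential2D:
    """The shipped rugged funnel surface.

    Two deep wells anchor the benchmark: the start well at (3, 3) and the
    target well at the origin.  A deterministic pseudo-random field of
    shallow wells (fixed internal seed, independent of simulation seeds)
    roughens the terrain between them, and a weak harmonic confinement
    keeps trajectories on the surface.
    """
    rng = np.random.default_rng(seed)
    wells = [
        GaussianWell(center=(3.0, 3.0), depth=10.0, width=0.16),  # start
        GaussianWell(center=(0.0, 0.0), depth=9.0, width=0.35),   # target
    ]
    # metastable stepping stones along the diagonal funnel: deep and narrow
    # enough that a serial trajectory stalls for tens of time units at each
    # barrier, close enough that a reseeding round (all trajectories
    # restarted at the frontier stone) crosses within a few rounds
    for k in range(1, 6):
        c = 0.5 * k
        wells.append(GaussianWell(center=(c, c), depth=10.0, width=0.16))
    # shallow ruggedness decorating the corridor (deterministic field)
    for _ in range(18):
        cx, cy = rng.uniform(0.0, 3.0, size=2)
        if min(np.hypot(cx - 3, cy - 3), np.hypot(cx, cy)) < 0.5:
            continue
        wells.append(GaussianWell(center=(float(cx), float(cy)),
                                  depth=float(rng.uniform(0.5, 1.5)),
                                  width=float(rng.uniform(0.15, 0.25))))
    return Potential2D(tuple(wells), confinement_center=(1.5, 1.5),
                       confinement_stiffness=0.3, channel_stiffness=3.0,
                       start_well=0, target_well=1)


def default_params(seed: int = 0, n_steps: int = 300_000) -> BrownianParams:
    return BrownianParams(diffusion=1.0, dt=2e-4, kT=1.0,
                          n_steps=n_steps, seed=seed)


def save_potential(p: Potential2D, path) -> None:
    doc = {
        "wells": [{"center": list(map(float, w.center)),
                   "depth": float(w.depth), "width": float(w.width)}
                  for w in p.wells],
        "confinement": {
            "center": list(map(float, p.confinement_center or (0, 0))),
            "stiffness": float(p.confinement_stiffness)},
        "channel_stiffness": float(p.channel_stiffness),
        "start_well": p.start_well,
        "target_well": p.target_well,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_potential(path) -> Potential2D:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    wells = tuple(GaussianWell(tuple(w["center"]), w["depth"], w["width"])
                  for w in doc["wells"])
    conf = doc.get("confinement") or {}
    return Potential2D(
        wells,
        confinement_center=tuple(conf.get("center", (0, 0))),
        confinement_stiffness=float(conf.get("stiffness", 0.0)),
        channel_stiffness=float(doc.get("channel_stiffness", 0.0)),
        start_well=int(doc.get("start_well", 0)),
        target_well=int(doc.get("target_well", 1)),
    )
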