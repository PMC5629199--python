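"""Structures, coupled-pair distances, superposition RMSD, featurization.

PDB files are parsed with Biopython (first model, highest-occupancy altloc)
into a lightweight :class:`Structure` that keeps atoms in file order.  On
top of it this module provides the geometry the sampling pipeline needs:

* coupled-pair distances (Calpha-Calpha by default, or closest heavy atom),
  the raw ingredient of the SEC/dSEC score;
* optimal-superposition RMSD (Kabsch);
* the three featurization schemes used for Markov-state-model construction:
  backbone/chi1 dihedrals encoded as (sin, cos), reciprocal interatomic
  distances, and the center-of-mass-in-local-basis coordinates used for
  protein-protein association.

Coupling tables index alignment positions, not author residue numbers, so
coupling index k maps to the k-th resolved residue of a chain (optionally
shifted by an explicit offset).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.SVDSuperimposer import SVDSuperimposer

from .couplings import CouplingSet
from .errors import (EmptyInputError, FeaturizationError, MappingError,
                     SelectionError)

__all__ = [
    "Atom",
    "Structure",
    "DistanceSpec",
    "FeatureTrajectory",
    "read_pdb",
    "pair_distances",
    "superpose_rmsd",
    "kabsch_rmsd",
    "featurize",
]

log = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
# first side-chain gamma atom defining chi1, by preference order
_GAMMA_ATOMS = ("CG", "CG1", "OG", "OG1", "SG")
_ATOM_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845}


@dataclass(frozen=True)
class Atom:
    name: str
    resname: str
    resseq: int
    chain: str
    icode: str
    occupancy: float
    xyz: tuple  # (x, y, z) in Angstrom


@dataclass(frozen=True)
class Structure:
    """One model's atoms, in file order."""

    atoms: tuple
    model_id: int = 0

    def __len__(self):
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def chains(self):
        seen = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def residues(self, chain: Optional[str] = None):
        """Residues as ((chain, resseq, icode, resname), atoms) in file order."""
        out, index = [], {}
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            key = (a.chain, a.resseq, a.icode)
            if key not in index:
                index[key] = len(out)
                out.append(((a.chain, a.resseq, a.icode, a.resname), []))
            out[index[key]][1].append(a)
        return out

    def transformed(self, rotation: np.ndarray, translation) -> "Structure":
        """Rigidly transformed copy: x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = [Atom(a.name, a.resname, a.resseq, a.chain, a.icode, a.occupancy,
                    tuple(R @ np.asarray(a.xyz) + t)) for a in self.atoms]
        return Structure(tuple(new), self.model_id)


@dataclass(frozen=True)
class DistanceSpec:
    """How to turn a residue pair into one distance.

    mode "CA" measures Calpha-Calpha; "closest_heavy" takes the minimum over
    all non-hydrogen atom pairs.  ``offset`` shifts coupling indices before
    mapping onto each chain's resolved residues (coupling index k -> the
    (k + offset)-th resolved residue, 1-based).
    """

    mode: str = "CA"
    offset: int = 0

    def __post_init__(self):
        if self.mode not in ("CA", "closest_heavy"):
            raise ValueError(f"unknown distance mode {self.mode!r}")


@dataclass
class FeatureTrajectory:
    """frames x features matrix with labels and the frame time interval."""

    values: np.ndarray
    labels: tuple
    frame_interval: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (frames x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count does not match feature count")

    @property
    def n_frames(self):
        return self.values.shape[0]


def read_pdb(path) -> Structure:
    """Parse a PDB file: first model only, highest-occupancy altloc kept."""
    parser = PDBParser(QUIET=True)
    model = next(iter(parser.get_structure("s", path)))
    atoms = []
    for chain in model:
        for res in chain:
            for atom in res:  # Biopython yields the highest-occupancy altloc
                if atom.is_disordered():
                    atom = atom.selected_child
                het, resseq, icode = res.get_id()
                atoms.append(Atom(
                    name=atom.get_name(),
                    resname=res.get_resname(),
                    resseq=resseq,
                    chain=chain.get_id(),
                    icode=icode.strip(),
                    occupancy=float(atom.get_occupancy() or 1.0),
                    xyz=tuple(float(v) for v in atom.get_coord()),
                ))
    if not atoms:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    return Structure(tuple(atoms), model_id=model.get_id())


def _chain_residues(s: Structure, chain: str):
    res = s.residues(chain)
    if not res:
        raise MappingError(f"chain {chain!r} not found in structure")
    return res


def _resolve(s: Structure, chain: str, index: int, offset: int):
    """Map a 1-based coupling index to a residue's atoms."""
    res = _chain_residues(s, chain)
    k = index + offset
    if not 1 <= k <= len(res):
        raise MappingError(
            f"residue index {index} (offset {offset}) outside chain {chain!r} "
            f"with {len(res)} resolved residues")
    return res[k - 1][1]


def _heavy(atoms):
    return [a for a in atoms if not a.name.startswith("H")]


def _residue_point(atoms, mode: str, where: str) -> Optional[np.ndarray]:
    if mode == "CA":
        for a in atoms:
            if a.name == "CA":
                return np.asarray(a.xyz)
        return None
    return None  # closest_heavy handled pairwise


def pair_distances(s: Structure, pairs: CouplingSet,
                   spec: DistanceSpec = DistanceSpec()) -> np.ndarray:
    """Distances (Angstrom) for each coupled pair, in record order.

    Pairs without chain labels are resolved against the structure's first
    chain.  Unresolvable residues are reported together in one error.
    """
    default_chain = s.chains()[0]
    out = []
    missing = []
    for rec in pairs:
        ci = rec.chain_i or default_chain
        cj = rec.chain_j or default_chain
        try:
            atoms_i = _resolve(s, ci, rec.residue_i, spec.offset)
            atoms_j = _resolve(s, cj, rec.residue_j, spec.offset)
        except MappingError as exc:
            missing.append(str(exc))
            continue
        if spec.mode == "CA":
            pi = _residue_point(atoms_i, "CA", "i")
            pj = _residue_point(atoms_j, "CA", "j")
            if pi is None or pj is None:
                missing.append(f"pair {rec.pair}: missing CA atom")
                continue
            out.append(float(np.linalg.norm(pi - pj)))
        else:
            hi, hj = _heavy(atoms_i), _heavy(atoms_j)
            if not hi or not hj:
                missing.append(f"pair {rec.pair}: no heavy atoms")
                continue
            xi = np.array([a.xyz for a in hi])
            xj = np.array([a.xyz for a in hj])
            d = np.linalg.norm(xi[:, None, :] - xj[None, :, :], axis=-1)
            out.append(float(d.min()))
    if missing:
        raise MappingError("unresolvable pairs:\n  " + "\n  ".join(missing))
    return np.asarray(out)


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """RMSD between two (n, 3) point sets after optimal rigid superposition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise SelectionError(f"point sets differ in shape: {x.shape} vs {y.shape}")
    sup = SVDSuperimposer()
    sup.set(x, y)
    sup.run()
    return float(sup.get_rms())


def superpose_rmsd(a: Structure, b: Structure,
                   selection: Iterable[str] = BACKBONE_ATOMS) -> float:
    """Least-squares superposition RMSD over atoms matched by identity.

    Atoms are matched between the two structures by (chain, resseq, icode,
    atom name) over the names in ``selection`` (backbone N/CA/C/O by
    default); only atoms present in both structures enter the fit.
    """
    names = set(selection)

    def keyed(s):
        return {(at.chain, at.resseq, at.icode, at.name): np.asarray(at.xyz)
                for at in s.atoms if at.name in names}

    ka, kb = keyed(a), keyed(b)
    common = sorted(set(ka) & set(kb))
    if not common:
        raise SelectionError("no atoms in common under the given selection")
    return kabsch_rmsd(np.array([ka[k] for k in common]),
                       np.array([kb[k] for k in common]))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in radians for four points (IUPAC convention)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return math.atan2(np.dot(np.cross(b1n, v), w), np.dot(v, w))


def _atom_mass(name: str) -> float:
    el = name[:2].upper() if name[:2].upper() in ("SE", "FE") else name[0].upper()
    return _ATOM_MASSES.get(el, 12.011)


def center_of_mass(atoms) -> np.ndarray:
    m = np.array([_atom_mass(a.name) for a in atoms], float)
    x = np.array([a.xyz for a in atoms], float)
    return (m[:, None] * x).sum(axis=0) / m.sum()


def _dihedral_features(s: Structure):
    """phi, psi, chi1 per residue, encoded as (sin, cos) pairs."""
    feats, labels = [], []
    for chain in s.chains():
        res = s.residues(chain)
        bb = []
        for (_, _, _, _), atoms in res:
            d = {a.name: np.asarray(a.xyz) for a in atoms}
            bb.append(d)
        for i, ((ch, seq, ic, rname), atoms) in enumerate(res):
            d = bb[i]
            tag = f"{ch}{seq}{ic}"
            if i > 0 and all(k in bb[i - 1] for k in ("C",)) and \
                    all(k in d for k in ("N", "CA", "C")):
                ang = dihedral(bb[i - 1]["C"], d["N"], d["CA"], d["C"])
                feats += [math.sin(ang), math.cos(ang)]
                labels += [f"phi_{tag}_sin", f"phi_{tag}_cos"]
            if i + 1 < len(res) and "N" in bb[i + 1] and \
                    all(k in d for k in ("N", "CA", "C")):
                ang = dihedral(d["N"], d["CA"], d["C"], bb[i + 1]["N"])
                feats += [math.sin(ang), math.cos(ang)]
                labels += [f"psi_{tag}_sin", f"psi_{tag}_cos"]
            gamma = next((g for g in _GAMMA_ATOMS if g in d), None)
            if gamma and all(k in d for k in ("N", "CA", "CB")):
                ang = dihedral(d["N"], d["CA"], d["CB"], d[gamma])
                feats += [math.sin(ang), math.cos(ang)]
                labels += [f"chi1_{tag}_sin", f"chi1_{tag}_cos"]
            elif rname in ("GLY", "ALA"):
                log.debug("no chi1 for %s %s (dropped)", rname, tag)
    return np.asarray(feats), tuple(labels)


def _reciprocal_features(s: Structure, atom_name: str = "CA"):
    pts = [(f"{a.chain}{a.resseq}{a.icode}", np.asarray(a.xyz))
           for a in s.atoms if a.name == atom_name]
    if len(pts) < 2:
        raise FeaturizationError(
            f"fewer than two {atom_name} atoms for reciprocal distances")
    feats, labels = [], []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = float(np.linalg.norm(pts[i][1] - pts[j][1]))
            if d == 0:
                raise FeaturizationError(
                    f"coincident atoms {pts[i][0]}, {pts[j][0]}")
            feats.append(1.0 / d)
            labels.append(f"rinv_{pts[i][0]}_{pts[j][0]}")
    return np.asarray(feats), tuple(labels)


def local_basis(anchors: np.ndarray) -> np.ndarray:
    """Orthonormal basis (columns) from three anchor points by Gram-Schmidt."""
    a = np.asarray(anchors, float)
    u1 = a[1] - a[0]
    n1 = np.linalg.norm(u1)
    if n1 < 1e-9:
        raise FeaturizationError("anchor residues coincide")
    e1 = u1 / n1
    u2 = a[2] - a[0]
    u2 = u2 - np.dot(u2, e1) * e1
    n2 = np.linalg.norm(u2)
    if n2 < 1e-9:
        raise FeaturizationError("anchor residues are collinear: degenerate basis")
    e2 = u2 / n2
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _com_basis_features(s: Structure, base_chain: str, partner_chain: str,
                        anchors: Sequence[int]):
    """Partner COM minus base COM, expressed in the base chain's local basis.

    ``anchors`` are three 1-based residue indices on the base chain whose
    alpha-carbons define the orthonormal frame.  Because the frame co-rotates
    with the base chain, the three features are invariant under rigid motion
    of the whole complex.
    """
    if len(anchors) != 3:
        raise FeaturizationError("com_basis needs exactly three anchor residues")
    res = _chain_residues(s, base_chain)
    pts = []
    for k in anchors:
        if not 1 <= k <= len(res):
            raise FeaturizationError(
                f"anchor residue {k} outside base chain ({len(res)} residues)")
        ca = next((a for a in res[k - 1][1] if a.name == "CA"), None)
        if ca is None:
            raise FeaturizationError(f"anchor residue {k} has no CA atom")
        pts.append(ca.xyz)
    basis = local_basis(np.asarray(pts))
    base_atoms = [a for a in s.atoms if a.chain == base_chain]
    partner_atoms = [a for a in s.atoms if a.chain == partner_chain]
    if not partner_atoms:
        raise FeaturizationError(f"partner chain {partner_chain!r} not found")
    diff = center_of_mass(partner_atoms) - center_of_mass(base_atoms)
    feats = basis.T @ diff
    return feats, ("com_b1", "com_b2", "com_b3")


def featurize(traj: Sequence[Structure], scheme: str,
              frame_interval: float = 1.0, **params) -> FeatureTrajectory:
    """Featurize a sequence of structures.

    scheme "dihedral": per-residue phi, psi, chi1 angles as (sin, cos) pairs
    (residues lacking a chi1 gamma atom contribute no chi1 features);
    "reciprocal_distance": 1/d over all alpha-carbon pairs (``atom_name``
    overrides); "com_basis": partner-chain center-of-mass displacement in the
    base chain's anchor frame (requires ``base_chain``, ``partner_chain``,
    ``anchors``: three 1-based residue indices).
    """
    traj = list(traj)
    if not traj:
        raise EmptyInputError("empty trajectory")
    rows, labels = [], None
    for s in traj:
        if scheme == "dihedral":
            f, lab = _dihedral_features(s)
        elif scheme == "reciprocal_distance":
            f, lab = _reciprocal_features(s, params.get("atom_name", "CA"))
        elif scheme == "com_basis":
            f, lab = _com_basis_features(
                s, params["base_chain"], params["partner_chain"], params["anchors"])
        else:
            raise ValueError(f"unknown featurization scheme {scheme!r}")
        if labels is None:
            labels = lab
        elif lab != labels:
            raise FeaturizationError(
                "feature set changes between frames (missing atoms?)")
        rows.append(f)
    return FeatureTrajectory(np.vstack(rows), labels, frame_interval)
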