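"""Evolutionary-coupling tables and the dSEC guidance score.

Evolutionary couplings (ECs) are statistical dependencies between residue
positions inferred from multiple sequence alignments; strongly coupled pairs
tend to be in physical contact in functional conformations.  This module
reads ranked EC score tables (EVcouplings-style CSV, intra-chain or
inter-chain "complex" dialect), selects the pairs to use for sampling, and
computes the guidance score

    SEC  = sum of distances between all selected coupled pairs in a frame
    dSEC = SEC(frame) - SEC(reference structure)

dSEC > 0 means the frame is farther than the reference from the coupled-pair
contact geometry; adaptive strategies consume it with either max (explore
away from a known state) or min (fold/associate toward contacts) semantics.

Coupling tables use 1-based residue indices as produced by alignment
pipelines; mapping those indices onto structure numbering is the job of
:mod:`ecsampler.structio`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError, FormatError, PairingError

__all__ = [
    "CouplingRecord",
    "CouplingSet",
    "SECScore",
    "read_coupling_table",
    "select_pairs",
    "delta_sec",
    "state_score",
]

DEFAULT_STATE_SAMPLES = 50  # member structures averaged per cluster score


@dataclass(frozen=True, order=True)
class CouplingRecord:
    """A single scored residue pair, stored in canonical order.

    Canonical order sorts the two endpoints by (chain label, residue index)
    so that (j, i) and (i, j) denote the same record.  Indices are 1-based.
    """

    sort_index: tuple = field(init=False, repr=False)
    residue_i: int
    residue_j: int
    score: float
    chain_i: Optional[str] = None
    chain_j: Optional[str] = None

    def __post_init__(self):
        ci = self.chain_i or ""
        cj = self.chain_j or ""
        if (cj, self.residue_j) < (ci, self.residue_i):
            ri, rj = self.residue_i, self.residue_j
            chi, chj = self.chain_i, self.chain_j
            object.__setattr__(self, "residue_i", rj)
            object.__setattr__(self, "residue_j", ri)
            object.__setattr__(self, "chain_i", chj or None)
            object.__setattr__(self, "chain_j", chi or None)
        if self.chain_i == self.chain_j and self.residue_i == self.residue_j:
            raise DomainError(
                f"self-pair ({self.chain_i}, {self.residue_i}) is not a coupling"
            )
        if not np.isfinite(self.score):
            raise DomainError(f"non-finite coupling score for pair {self.pair}")
        object.__setattr__(self, "sort_index", (-self.score,) + self.pair)

    @property
    def pair(self) -> tuple:
        return (self.chain_i or "", self.residue_i, self.chain_j or "", self.residue_j)


@dataclass(frozen=True)
class CouplingSet:
    """Ranked coupling records, descending by score.

    Ties are broken by canonical pair order so that selection by ``top_n``
    is reproducible.  ``selection`` records how the set was derived
    (e.g. ``"top_n=800"`` or ``"cutoff=0.012"``); ``source`` is provenance.
    """

    records: tuple
    selection: str = "all"
    source: str = ""

    def __post_init__(self):
        recs = tuple(sorted(self.records))
        pairs = [r.pair for r in recs]
        if len(set(pairs)) != len(pairs):
            dup = next(p for p in pairs if pairs.count(p) > 1)
            raise FormatError(f"duplicate coupling pair {dup}")
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.records], dtype=float)


@dataclass(frozen=True)
class SECScore:
    """Sum of coupled-pair distances and its change relative to a reference."""

    sec: float
    delta_sec: float
    reference_id: str = ""


def read_coupling_table(path, dialect: str = "intra") -> CouplingSet:
    """Read an EVcouplings-style CSV of scored residue pairs.

    Parameters
    ----------
    path
        CSV with a header row.  The ``intra`` dialect expects columns
        ``i, j, score``; the ``complex`` dialect (inter-chain "EV complex"
        scores) expects ``chain_i, i, chain_j, j, score``.
    dialect
        ``"intra"`` or ``"complex"``.

    Returns
    -------
    CouplingSet sorted descending by score, residue indices kept 1-based.
    """
    if dialect not in ("intra", "complex"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"coupling table {path} is empty")
    needed = ["i", "j", "score"] if dialect == "intra" else [
        "chain_i", "i", "chain_j", "j", "score"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(
            f"coupling table {path} lacks column(s) {missing}; found {list(df.columns)}"
        )
    if len(df) == 0:
        raise EmptyInputError(f"coupling table {path} has a header but no rows")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            i, j = int(d["i"]), int(d["j"])
            score = float(d["score"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} line {row_no}: {exc}") from exc
        if not np.isfinite(score):
            raise FormatError(f"{path} line {row_no}: non-finite score")
        chain_i = str(d["chain_i"]) if dialect == "complex" else None
        chain_j = str(d["chain_j"]) if dialect == "complex" else None
        try:
            records.append(CouplingRecord(i, j, score, chain_i, chain_j))
        except DomainError as exc:
            raise FormatError(f"{path} line {row_no}: {exc}") from exc
    return CouplingSet(tuple(records), selection="all", source=str(path))


def select_pairs(cs: CouplingSet, top_n: Optional[int] = None,
                 cutoff: Optional[float] = None) -> CouplingSet:
    """Select the coupled pairs to use for sampling.

    Exactly one of ``top_n`` (keep the n highest-scoring pairs) or
    ``cutoff`` (keep pairs with score >= cutoff) must be given.  Ties at a
    ``top_n`` boundary are resolved by canonical pair order, which is the
    order records are already stored in.
    """
    if (top_n is None) == (cutoff is None):
        raise ValueError("give exactly one of top_n or cutoff")
    if top_n is not None:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        if top_n > len(cs):
            warnings.warn(
                f"top_n={top_n} exceeds the {len(cs)} available couplings; "
                "returning all", stacklevel=2)
            top_n = len(cs)
        kept = cs.records[:top_n]
        sel = f"top_n={top_n}"
    else:
        kept = tuple(r for r in cs.records if r.score >= cutoff)
        if not kept:
            raise EmptyInputError(f"cutoff={cutoff} excludes every coupling")
        sel = f"cutoff={cutoff}"
    return replace(cs, records=kept, selection=sel)


def delta_sec(conf_distances, ref_distances, reference_id: str = "") -> SECScore:
    """Compute SEC and dSEC from per-pair distance vectors.

    Both vectors must list distances for the same pairs in the same order.
    dSEC = sum(conf) - sum(ref); positive means farther from the reference.
    """
    conf = np.asarray(conf_distances, dtype=float)
    ref = np.asarray(ref_distances, dtype=float)
    if conf.shape != ref.shape or conf.ndim != 1:
        raise PairingError(
            f"distance vectors differ in shape: {conf.shape} vs {ref.shape}")
    if conf.size and (conf.min() < 0 or ref.min() < 0):
        raise DomainError("distances must be non-negative")
    sec = float(conf.sum())
    return SECScore(sec=sec, delta_sec=sec - float(ref.sum()),
                    reference_id=reference_id)


def state_score(member_confs: Sequence, ref, n_samples: int = DEFAULT_STATE_SAMPLES,
                rng_seed: int = 0, reference_id: str = "") -> float:
    """Average dSEC over randomly chosen member structures of a cluster.

    ``member_confs`` holds one per-pair distance vector per member frame.
    min(n_samples, len(members)) members are drawn uniformly without
    replacement under ``rng_seed``; clusters smaller than ``n_samples`` use
    every member, making the score the exact cluster mean.
    """
    if len(member_confs) == 0:
        raise EmptyInputError("cluster has no member structures")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng_seed)
    take = min(n_samples, len(member_confs))
    idx = rng.choice(len(member_confs), size=take, replace=False)
    vals = [delta_sec(member_confs[i], ref, reference_id).delta_sec for i in idx]
    return float(np.mean(vals))
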