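"""Static atom/residue metadata shared by every frame of a trajectory.

A :class:`Topology` stores, per atom: name, element, residue number/name,
chain id, integer formal charge, and role flags (hydrogen-bond donor,
acceptor, hydrogen, backbone, aromatic-ring member).  Each hydrogen records
the index of the heavy atom it is bonded to, which is the donor used by the
geometric hydrogen-bond criterion.

Role flags are package metadata, not derivable from coordinates; they travel
in a JSON sidecar when trajectories are written to PDB/XYZ (neither format
can carry them).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import SelectionError, TopologyError

__all__ = ["Topology", "AtomSelection"]


def _as_array(values, dtype) -> np.ndarray:
    arr = np.asarray(values, dtype=dtype)
    if arr.ndim != 1:
        raise TopologyError("per-atom annotation must be one-dimensional")
    return arr


@dataclass
class Topology:
    """Per-atom metadata. All arrays share one length (the atom count)."""

    names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    charges: np.ndarray
    is_donor: np.ndarray
    is_acceptor: np.ndarray
    is_hydrogen: np.ndarray
    is_backbone: np.ndarray
    is_ring: np.ndarray
    hydrogen_donor: np.ndarray  # heavy-atom index per hydrogen, -1 elsewhere

    def __post_init__(self) -> None:
        self.names = _as_array(self.names, object)
        self.elements = _as_array(self.elements, object)
        self.res_ids = _as_array(self.res_ids, np.int64)
        self.res_names = _as_array(self.res_names, object)
        self.chain_ids = _as_array(self.chain_ids, object)
        self.charges = _as_array(self.charges, np.int64)
        for flag in ("is_donor", "is_acceptor", "is_hydrogen",
                     "is_backbone", "is_ring"):
            setattr(self, flag, _as_array(getattr(self, flag), bool))
        self.hydrogen_donor = _as_array(self.hydrogen_donor, np.int64)
        n = len(self.names)
        for name in ("elements", "res_ids", "res_names", "chain_ids",
                     "charges", "is_donor", "is_acceptor", "is_hydrogen",
                     "is_backbone", "is_ring", "hydrogen_donor"):
            if len(getattr(self, name)) != n:
                raise TopologyError(
                    f"annotation '{name}' has length {len(getattr(self, name))},"
                    f" expected {n}")
        # atom names unique within a residue
        seen: set[tuple] = set()
        for i in range(n):
            key = (self.chain_ids[i], self.res_ids[i], self.names[i])
            if key in seen:
                raise TopologyError(
                    f"duplicate atom name {self.names[i]!r} in residue "
                    f"{self.res_names[i]}-{self.res_ids[i]}")
            seen.add(key)
        # a hydrogen's recorded donor must be a real, non-hydrogen atom
        for i in np.flatnonzero(self.hydrogen_donor >= 0):
            j = self.hydrogen_donor[i]
            if j >= n or self.is_hydrogen[j]:
                raise TopologyError(
                    f"hydrogen {self.names[i]!r} bonded to invalid donor index {j}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Sequence[Mapping]) -> "Topology":
        """Build from a list of per-atom dicts (missing keys get defaults)."""
        def col(key, default):
            return [a.get(key, default) for a in atoms]

        return cls(
            names=col("name", "X"),
            elements=col("element", "C"),
            res_ids=col("res_id", 1),
            res_names=col("res_name", "UNK"),
            chain_ids=col("chain_id", "A"),
            charges=col("charge", 0),
            is_donor=col("donor", False),
            is_acceptor=col("acceptor", False),
            is_hydrogen=col("hydrogen", False),
            is_backbone=col("backbone", False),
            is_ring=col("ring", False),
            hydrogen_donor=col("hydrogen_donor", -1),
        )

    # -- selections -----------------------------------------------------------

    def select(self, *, name=None, res_name=None, res_id=None, chain_id=None,
               role: str | None = None) -> np.ndarray:
        """Indices of atoms matching every given criterion.

        ``name``/``res_name``/``res_id``/``chain_id`` accept a scalar or an
        iterable of allowed values; ``role`` is one of ``donor``, ``acceptor``,
        ``hydrogen``, ``backbone``, ``ring``.
        """
        mask = np.ones(self.n_atoms, dtype=bool)

        def narrow(column, allowed):
            nonlocal mask
            if allowed is None:
                return
            if isinstance(allowed, (str, int, np.integer)):
                allowed = [allowed]
            mask &= np.isin(column, list(allowed))

        narrow(self.names, name)
        narrow(self.res_names, res_name)
        narrow(self.res_ids, res_id)
        narrow(self.chain_ids, chain_id)
        if role is not None:
            try:
                mask &= getattr(self, f"is_{role}")
            except AttributeError:
                raise SelectionError(f"unknown role flag {role!r}") from None
        return np.flatnonzero(mask)

    def residue_atoms(self, residues: Iterable[tuple[str, int]]) -> np.ndarray:
        """Indices of all atoms belonging to any of the (res_name, res_id) pairs."""
        wanted = {(str(rn), int(ri)) for rn, ri in residues}
        mask = np.array(
            [(self.res_names[i], int(self.res_ids[i])) in wanted
             for i in range(self.n_atoms)], dtype=bool)
        return np.flatnonzero(mask)

    def index_of(self, name: str, res_id: int | None = None) -> int:
        """Index of the uniquely named atom; raises SelectionError if absent."""
        idx = self.select(name=name, res_id=res_id)
        if len(idx) == 0:
            raise SelectionError(f"atom {name!r}"
                                 + (f" in residue {res_id}" if res_id else "")
                                 + " not found in topology")
        if len(idx) > 1:
            raise SelectionError(f"atom name {name!r} is ambiguous; "
                                 "give res_id to disambiguate")
        return int(idx[0])

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "names": self.names.tolist(),
            "elements": self.elements.tolist(),
            "res_ids": self.res_ids.tolist(),
            "res_names": self.res_names.tolist(),
            "chain_ids": self.chain_ids.tolist(),
            "charges": self.charges.tolist(),
            "is_donor": self.is_donor.tolist(),
            "is_acceptor": self.is_acceptor.tolist(),
            "is_hydrogen": self.is_hydrogen.tolist(),
            "is_backbone": self.is_backbone.tolist(),
            "is_ring": self.is_ring.tolist(),
            "hydrogen_donor": self.hydrogen_donor.tolist(),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Topology":
        return cls(**{k: data[k] for k in (
            "names", "elements", "res_ids", "res_names", "chain_ids",
            "charges", "is_donor", "is_acceptor", "is_hydrogen",
            "is_backbone", "is_ring", "hydrogen_donor")})

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def read_json(cls, path) -> "Topology":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class AtomSelection:
    """A reusable predicate over a topology, resolved to an index list.

    Criteria combine with logical AND; ``indices`` short-circuits resolution.
    """

    name: object = None
    res_name: object = None
    res_id: object = None
    chain_id: object = None
    role: str | None = None
    indices: Sequence[int] | None = field(default=None)

    def resolve(self, topology: Topology) -> np.ndarray:
        if self.indices is not None:
            idx = np.asarray(self.indices, dtype=np.int64)
            if len(np.unique(idx)) != len(idx):
                raise SelectionError("selection indices are not unique")
            if len(idx) and (idx.min() < 0 or idx.max() >= topology.n_atoms):
                raise SelectionError("selection index out of range")
            return idx
        return topology.select(name=self.name, res_name=self.res_name,
                               res_id=self.res_id, chain_id=self.chain_id,
                               role=self.role)
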