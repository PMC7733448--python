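"""Trajectory container and the geometric primitives built on it.

Coordinates are stored in Å, times in ns, package-wide.  The operations here
are the ones the downstream stages consume: mass-weighted centers of mass,
Kabsch least-squares superposition with RMSD, the per-frame RMSD series
against the first frame, and the release reaction coordinate — the distance
between arm atom N17 and the center of mass of residues Glu-12 and Glu-14,
whose time course tracks the arm leaving the cavity of protein H.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, SelectionError
from .topology import AtomSelection, Topology

__all__ = [
    "Trajectory", "ScalarSeries", "center_of_mass", "kabsch_superpose",
    "rmsd_series", "reaction_coordinate",
]

# standard atomic masses for the elements the toy systems use; unit mass
# otherwise (toy beads carry no real element identity)
_ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                   "S": 32.06, "P": 30.974}


@dataclass
class Trajectory:
    """Ordered frames of 3D coordinates (Å) with timestamps (ns)."""

    coords: np.ndarray      # (n_frames, n_atoms, 3)
    times: np.ndarray       # (n_frames,), strictly increasing
    topology: Topology

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] != len(self.times):
            raise ValueError("times length must equal frame count")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} != topology atom "
                f"count {self.topology.n_atoms}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass
class ScalarSeries:
    """A per-frame scalar observable (RMSD, distance, ...)."""

    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values contain non-finite entries")

    def __len__(self) -> int:
        return len(self.values)


def _resolve(selection, topology: Topology) -> np.ndarray:
    if selection is None:
        return np.arange(topology.n_atoms)
    if isinstance(selection, AtomSelection):
        return selection.resolve(topology)
    return np.asarray(selection, dtype=np.int64)


def _masses_for(topology: Topology, indices: np.ndarray,
                masses) -> np.ndarray:
    if masses is not None:
        m = np.asarray(masses, dtype=np.float64)
        if len(m) != len(indices):
            raise SelectionError("masses length must match selection length")
        return m
    # unit masses by default in toy systems; element masses on request are
    # available via explicit `masses=`
    return np.ones(len(indices))


def element_masses(topology: Topology, indices=None) -> np.ndarray:
    """Standard atomic masses for a selection (unit mass for unknown elements)."""
    idx = _resolve(indices, topology)
    return np.array([_ELEMENT_MASSES.get(str(e), 1.0)
                     for e in topology.elements[idx]])


def center_of_mass(frame: np.ndarray, selection, topology: Topology | None = None,
                   masses=None) -> np.ndarray:
    """Mass-weighted mean position of a selection within one frame.

    With ``masses=None`` every selected atom gets unit mass (the toy-system
    default); pass :func:`element_masses` output for physical weighting.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if topology is not None:
        idx = _resolve(selection, topology)
    else:
        idx = np.asarray(selection, dtype=np.int64)
    if len(idx) == 0:
        raise SelectionError("center_of_mass: empty selection")
    m = masses if masses is not None else np.ones(len(idx))
    m = np.asarray(m, dtype=np.float64)
    if len(m) != len(idx):
        raise SelectionError("masses length must match selection length")
    return (frame[idx] * m[:, None]).sum(axis=0) / m.sum()


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where
    ``rotation @ x + translation`` maps mobile coordinates onto the reference
    frame and ``rmsd`` is the post-fit RMSD over the selection.  The rotation
    is proper (det +1).  Requires at least three non-collinear selected atoms.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    idx = (np.arange(mobile.shape[0]) if selection is None
           else np.asarray(selection, dtype=np.int64))
    if len(idx) < 3:
        raise DegenerateGeometryError(
            f"superposition needs >= 3 atoms, got {len(idx)}")
    mob = mobile[idx]
    ref = reference[idx]
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinear (or coincident) selections leave the rotation underdetermined
    spread = max(np.linalg.norm(mob_c), np.linalg.norm(ref_c), 1.0)
    if (np.linalg.matrix_rank(mob_c, tol=1e-8 * spread) < 2
            or np.linalg.matrix_rank(ref_c, tol=1e-8 * spread) < 2):
        raise DegenerateGeometryError("selected atoms are collinear")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rmsd = rssd / np.sqrt(len(idx))
    rotation = rot.as_matrix()
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    return rotation, translation, float(rmsd)


def rmsd_series(traj: Trajectory, selection=None,
                reference: np.ndarray | None = None) -> ScalarSeries:
    """Per-frame post-superposition RMSD against a reference frame.

    The reference defaults to the first frame, so the series starts at zero.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory is empty")
    idx = _resolve(selection, traj.topology)
    ref = traj.coords[0] if reference is None else np.asarray(reference)
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, _, values[i] = kabsch_superpose(traj.coords[i], ref, idx)
    return ScalarSeries(times=traj.times, values=values, unit="A")


def reaction_coordinate(traj: Trajectory, arm_atom: str = "N17",
                        residue_group: Sequence[tuple[str, int]] = (
                            ("GLU", 12), ("GLU", 14)),
                        masses=None) -> ScalarSeries:
    """Distance from one arm atom to the COM of a residue group, per frame.

    Defaults reproduce the release coordinate: N17 of the aminomethyl lipoate
    arm versus the center of mass of all atoms of Glu-12 and Glu-14.
    """
    top = traj.topology
    atom_idx = top.index_of(arm_atom)
    group = top.residue_atoms(residue_group)
    if len(group) == 0:
        missing = ", ".join(f"{rn}-{ri}" for rn, ri in residue_group)
        raise SelectionError(f"residue group not found in topology: {missing}")
    m = _masses_for(top, group, masses)
    com = (traj.coords[:, group, :] * m[None, :, None]).sum(axis=1) / m.sum()
    dist = np.linalg.norm(traj.coords[:, atom_idx, :] - com, axis=1)
    return ScalarSeries(times=traj.times, values=dist, unit="A")
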