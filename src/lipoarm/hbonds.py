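"""Geometric hydrogen-bond detection and arm–cavity contact tables.

A hydrogen bond is recorded for every (donor, bonded hydrogen, acceptor)
triple whose donor–acceptor distance is at most ``r_DA`` and whose
H–donor–acceptor angle is at most ``theta_HDA``.  The defaults (3.5 Å, 30°)
follow the conventional gmx-hbond geometric criterion; they are configurable
and should be logged with every analysis.

A bond is "charged" when its donor or acceptor atom carries a nonzero formal
charge — the interactions that pin the positively charged nitrogen atoms of
the aminomethyl lipoate arm (N17, N6) to the polar cavity residues of
protein H are of this kind, and they are the signal the state segmentation
reads.  An optional toggle widens the rule to whole-residue formal charge so
carboxylates whose charge is annotated on a different oxygen still count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError, TopologyError
from .topology import AtomSelection, Topology
from .trajectory import Trajectory

__all__ = [
    "HBondCriteria", "HBondRecord", "ContactTable",
    "detect_hbonds", "classify_charged", "contact_table",
    "pi_sulfur_contacts",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoffs: donor–acceptor distance (Å), H–D–A angle (deg)."""

    max_da_distance: float = 3.5
    max_hda_angle: float = 30.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ParameterError("max_da_distance must be positive")
        if not 0 < self.max_hda_angle <= 90:
            raise ParameterError("max_hda_angle must be in (0, 90] degrees")


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    distance: float   # donor–acceptor, Å
    angle: float      # H–donor–acceptor, degrees
    charged: bool


def _triples(topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    """(hydrogen, donor) index pairs for every hydrogen on a flagged donor."""
    h_idx = np.flatnonzero(topology.is_hydrogen)
    if len(h_idx) and np.any(topology.hydrogen_donor[h_idx] < 0):
        bad = h_idx[topology.hydrogen_donor[h_idx] < 0][0]
        raise TopologyError(
            f"hydrogen {topology.names[bad]!r} (index {bad}) has no bonded donor")
    donors = topology.hydrogen_donor[h_idx]
    keep = topology.is_donor[donors]
    return h_idx[keep], donors[keep]


def _geometry(coords: np.ndarray, h_idx: np.ndarray, d_idx: np.ndarray,
              a_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distances and H–D–A angles for all (donor-H) x acceptor combinations.

    ``coords`` may be a single frame (n_atoms, 3) or a stack
    (n_frames, n_atoms, 3); outputs broadcast accordingly with trailing
    shape (n_donor_h, n_acceptors).
    """
    d_pos = coords[..., d_idx, :]                        # (..., nd, 3)
    h_pos = coords[..., h_idx, :]
    a_pos = coords[..., a_idx, :]                        # (..., na, 3)
    da = a_pos[..., None, :, :] - d_pos[..., :, None, :]  # (..., nd, na, 3)
    dist = np.linalg.norm(da, axis=-1)
    dh = h_pos - d_pos                                    # (..., nd, 3)
    dh_norm = np.linalg.norm(dh, axis=-1)
    cosang = np.einsum("...ij,...ikj->...ik", dh, da) / np.maximum(
        dh_norm[..., None] * dist, 1e-12)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return dist, angle


def classify_charged(record: HBondRecord, topology: Topology,
                     residue_charge: bool = False) -> bool:
    """True iff the bond's donor or acceptor is formally charged.

    With ``residue_charge=True`` the net formal charge of the donor's and
    acceptor's residues is considered instead of the single atoms, so a
    carboxylate whose -1 sits on the other oxygen still classifies as charged.
    """
    if record.charged and not residue_charge:
        return True
    if not residue_charge:
        return bool(topology.charges[record.donor]
                    or topology.charges[record.acceptor])
    for atom in (record.donor, record.acceptor):
        res_mask = ((topology.res_ids == topology.res_ids[atom])
                    & (topology.chain_ids == topology.chain_ids[atom]))
        if topology.charges[res_mask].sum() != 0:
            return True
    return False


def detect_hbonds(frame: np.ndarray, topology: Topology,
                  criteria: HBondCriteria = HBondCriteria(),
                  frame_index: int = 0) -> list[HBondRecord]:
    """All hydrogen bonds in one frame, exhaustively over flagged triples."""
    h_idx, d_idx = _triples(topology)
    a_idx = np.flatnonzero(topology.is_acceptor)
    if len(h_idx) == 0 or len(a_idx) == 0:
        return []
    dist, angle = _geometry(np.asarray(frame, dtype=np.float64),
                            h_idx, d_idx, a_idx)
    ok = ((dist <= criteria.max_da_distance)
          & (angle <= criteria.max_hda_angle)
          & (d_idx[:, None] != a_idx[None, :]))
    records = []
    for i, j in zip(*np.nonzero(ok)):
        d, h, a = int(d_idx[i]), int(h_idx[i]), int(a_idx[j])
        charged = bool(topology.charges[d] or topology.charges[a])
        records.append(HBondRecord(frame=frame_index, donor=d, hydrogen=h,
                                   acceptor=a, distance=float(dist[i, j]),
                                   angle=float(angle[i, j]), charged=charged))
    return records


@dataclass
class ContactTable:
    """Per-frame arm–cavity hydrogen bonds in long format.

    ``records`` columns: frame, time_ns, donor, hydrogen, acceptor (indices),
    donor_name, acceptor_name, acceptor_res / donor_res (residue labels),
    arm_atom, cavity_res_name, cavity_res_id, distance_A, angle_deg, charged.
    """

    records: pd.DataFrame
    n_frames: int
    times: np.ndarray

    def occupancy(self, t_start: float | None = None,
                  t_end: float | None = None) -> pd.DataFrame:
        """Fraction of frames in [t_start, t_end) bonding each (arm atom,
        cavity residue) pair."""
        mask = np.ones(self.n_frames, dtype=bool)
        if t_start is not None:
            mask &= self.times >= t_start
        if t_end is not None:
            mask &= self.times < t_end
        total = int(mask.sum())
        frames_in = set(np.flatnonzero(mask))
        rows = []
        if total:
            sub = self.records[self.records["frame"].isin(frames_in)]
            grouped = sub.groupby(
                ["arm_atom", "cavity_res_name", "cavity_res_id"])["frame"]
            for key, frames in grouped:
                rows.append({"arm_atom": key[0], "cavity_res_name": key[1],
                             "cavity_res_id": int(key[2]),
                             "bonded_frames": int(frames.nunique()),
                             "total_frames": total,
                             "occupancy": frames.nunique() / total})
        return pd.DataFrame(
            rows, columns=["arm_atom", "cavity_res_name", "cavity_res_id",
                           "bonded_frames", "total_frames", "occupancy"])

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def contact_table(traj: Trajectory,
                  criteria: HBondCriteria = HBondCriteria(),
                  arm_selection=None, cavity_selection=None,
                  residue_charge: bool = False) -> ContactTable:
    """Hydrogen bonds between arm atoms and cavity residues over all frames.

    Detection runs over every flagged (donor, hydrogen, acceptor) triple and
    is then restricted to pairs with one side in the arm selection and the
    other in the cavity selection.  Selections must be nonempty and disjoint.
    """
    top = traj.topology
    arm = (AtomSelection(chain_id="L").resolve(top) if arm_selection is None
           else _resolve_sel(arm_selection, top))
    cavity = (AtomSelection(chain_id="A").resolve(top)
              if cavity_selection is None
              else _resolve_sel(cavity_selection, top))
    if len(arm) == 0:
        raise SelectionError("arm selection is empty")
    if len(cavity) == 0:
        raise SelectionError("cavity selection is empty")
    if np.intersect1d(arm, cavity).size:
        raise SelectionError("arm and cavity selections overlap")

    h_idx, d_idx = _triples(top)
    a_idx = np.flatnonzero(top.is_acceptor)
    arm_set, cav_set = set(arm.tolist()), set(cavity.tolist())

    rows: list[dict] = []
    if len(h_idx) and len(a_idx):
        dist, angle = _geometry(traj.coords, h_idx, d_idx, a_idx)
        in_arm_d = np.isin(d_idx, arm)
        in_cav_d = np.isin(d_idx, cavity)
        in_arm_a = np.isin(a_idx, arm)
        in_cav_a = np.isin(a_idx, cavity)
        cross = (in_arm_d[:, None] & in_cav_a[None, :]) | (
            in_cav_d[:, None] & in_arm_a[None, :])
        ok = ((dist <= criteria.max_da_distance)
              & (angle <= criteria.max_hda_angle)
              & (d_idx[:, None] != a_idx[None, :])
              & cross[None, :, :])
        for f, i, j in zip(*np.nonzero(ok)):
            d, h, a = int(d_idx[i]), int(h_idx[i]), int(a_idx[j])
            arm_atom = d if d in arm_set else a
            cav_atom = a if arm_atom == d else d
            rec = HBondRecord(frame=int(f), donor=d, hydrogen=h, acceptor=a,
                              distance=float(dist[f, i, j]),
                              angle=float(angle[f, i, j]),
                              charged=bool(top.charges[d] or top.charges[a]))
            rows.append({
                "frame": int(f), "time_ns": float(traj.times[f]),
                "donor": d, "hydrogen": h, "acceptor": a,
                "donor_name": str(top.names[d]),
                "acceptor_name": str(top.names[a]),
                "arm_atom": str(top.names[arm_atom]),
                "cavity_res_name": str(top.res_names[cav_atom]),
                "cavity_res_id": int(top.res_ids[cav_atom]),
                "distance_A": rec.distance, "angle_deg": rec.angle,
                "charged": classify_charged(rec, top, residue_charge),
            })
    columns = ["frame", "time_ns", "donor", "hydrogen", "acceptor",
               "donor_name", "acceptor_name", "arm_atom", "cavity_res_name",
               "cavity_res_id", "distance_A", "angle_deg", "charged"]
    df = pd.DataFrame(rows, columns=columns)
    return ContactTable(records=df, n_frames=traj.n_frames,
                        times=np.asarray(traj.times))


def _resolve_sel(selection, topology: Topology) -> np.ndarray:
    if isinstance(selection, AtomSelection):
        return selection.resolve(topology)
    return np.asarray(selection, dtype=np.int64)


def pi_sulfur_contacts(frame: np.ndarray, topology: Topology,
                       sulfur_selection, ring_residues,
                       max_dist: float = 5.5) -> list[dict]:
    """Sulfur–aromatic contacts by the centroid-distance criterion.

    A contact is reported when a selected sulfur lies within ``max_dist`` Å
    of the centroid of a ring residue's annotated ring atoms (at least five
    required).  This captures the S15–His-13 π–sulfur interaction that helps
    hold the arm in its protected state.
    """
    frame = np.asarray(frame, dtype=np.float64)
    sulfurs = _resolve_sel(sulfur_selection, topology)
    contacts = []
    for res_name, res_id in ring_residues:
        res_atoms = topology.residue_atoms([(res_name, res_id)])
        ring = res_atoms[topology.is_ring[res_atoms]]
        if len(ring) < 5:
            raise TopologyError(
                f"residue {res_name}-{res_id} has {len(ring)} annotated ring "
                "atoms; >= 5 required")
        centroid = frame[ring].mean(axis=0)
        for s in sulfurs:
            d = float(np.linalg.norm(frame[s] - centroid))
            if d <= max_dist:
                contacts.append({"sulfur": int(s),
                                 "sulfur_name": str(topology.names[s]),
                                 "ring_res_name": str(res_name),
                                 "ring_res_id": int(res_id),
                                 "distance_A": d})
    return contacts
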