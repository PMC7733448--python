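"""Toy structural trajectories realizing the hallmark bond of each state.

The generator builds an abstract H-protein cavity (chain A) and lipoate-arm
(chain L) geometry in which, frame by frame, exactly the hallmark hydrogen
bond of the scheduled state is realized (donor–acceptor 2.75 Å, H–D–A angle
0° before noise) while every other candidate arm–cavity pair violates the
detection criteria by a safety margin (≥ 0.5 Å beyond the 3.5 Å distance
cutoff or ≥ 15° beyond the 30° angle cutoff).  During State I the
N17–COM(Glu-12, Glu-14) distance is held at 2.77 Å — inside the 2.6–2.9 Å
protected-state band — and the S15 sulfur sits within π–sulfur range of the
His-13 ring.  Released frames place the whole arm far outside the cavity.

Gaussian coordinate noise (default σ = 0.05 Å) and hallmark "flicker"
(default probability 0.02: the donor is pushed out to 4.0 Å for one frame)
exercise the downstream smoothing without making planted-schedule recovery
ambiguous.  A build-time margin check brute-forces every donor–H–acceptor
triple of every noiseless state layout against the criteria, so the
one-hallmark-per-frame invariant is enforced by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError, ScheduleError, TopologyError
from ..topology import Topology
from ..trajectory import Trajectory
from .schedules import StateSchedule

__all__ = ["ToyComplexSpec", "default_toy_complex",
           "generate_release_trajectory", "HALLMARKS"]

# hallmark (donor arm atom, cavity residue, cavity acceptor atom) per state
HALLMARKS = {
    "I": ("N17", ("GLU", 12), "OE1"),
    "II": ("N17", ("SER", 67), "OG"),
    "III": ("N17", ("ASP", 68), "OD1"),
    "IV": ("N17", ("TYR", 70), "OH"),
    "V": ("N6", ("LEU", 35), "O"),
}

_BOND_LENGTH = 2.75     # realized donor-acceptor distance, Å
_FLICKER_DIST = 4.0     # donor-acceptor distance in a flicker frame, Å
_DH_LENGTH = 1.0        # donor-hydrogen distance, Å

# detection criteria plus the construction safety margins
_R_CUT, _R_MARGIN = 3.5, 0.5
_ANG_CUT, _ANG_MARGIN = 30.0, 15.0


def _his_ring() -> list[dict]:
    """Five-membered ring of His-13 in the plane z = 8, centroid near the
    State-I position of S15 (π–sulfur partner)."""
    centroid = np.array([0.75, 1.5, 8.0])
    names = ["CG", "ND1", "CD2", "CE1", "NE2"]
    atoms = []
    for i, name in enumerate(names):
        ang = 2 * np.pi * i / 5
        pos = centroid + 1.2 * np.array([np.cos(ang), np.sin(ang), 0.0])
        atoms.append({"name": name, "element": "N" if name[0] == "N" else "C",
                      "res_id": 13, "res_name": "HIS", "chain_id": "A",
                      "ring": True, "xyz": pos,
                      "donor": name == "ND1", "acceptor": name == "NE2"})
    # ND1 pseudo-hydrogen points out of the cavity (+z)
    nd1 = next(a for a in atoms if a["name"] == "ND1")
    atoms.append({"name": "HD1", "element": "H", "res_id": 13,
                  "res_name": "HIS", "chain_id": "A", "hydrogen": True,
                  "xyz": nd1["xyz"] + np.array([0.0, 0.0, 1.0]),
                  "parent": "ND1"})
    return atoms


def _cavity_atoms() -> list[dict]:
    """Static cavity scaffold: hallmark stations 6 Å apart on the +y axis,
    the Glu-12/Glu-14 protected-state site around the origin, Ala-66 and
    His-13 off-axis."""
    def atom(name, element, res_id, res_name, xyz, *, donor=False,
             acceptor=False, hydrogen=False, charge=0, parent=None):
        return {"name": name, "element": element, "res_id": res_id,
                "res_name": res_name, "chain_id": "A", "donor": donor,
                "acceptor": acceptor, "hydrogen": hydrogen, "charge": charge,
                "xyz": np.asarray(xyz, dtype=np.float64), "parent": parent}

    atoms = [
        # protected-state site: carboxylate oxygens flank the origin
        atom("OE1", "O", 12, "GLU", (1.5, 0, 0), acceptor=True, charge=-1),
        atom("N", "N", 12, "GLU", (2.6, 0, 0), donor=True) | {"backbone": True},
        atom("HN", "H", 12, "GLU", (2.6, 0, -1), hydrogen=True, parent="N"),
        atom("OE1", "O", 14, "GLU", (-1.5, 0, 0), acceptor=True, charge=-1),
        atom("N", "N", 14, "GLU", (-2.6, 0, 0), donor=True) | {"backbone": True},
        atom("HN", "H", 14, "GLU", (-2.6, 0, -1), hydrogen=True, parent="N"),
        # release path stations
        atom("OG", "O", 67, "SER", (0, 8, 0), donor=True, acceptor=True),
        atom("HG", "H", 67, "SER", (1, 8, 0), hydrogen=True, parent="OG"),
        atom("OD1", "O", 68, "ASP", (0, 14, 0), acceptor=True, charge=-1),
        atom("N", "N", 68, "ASP", (1.8, 14, -0.8), donor=True)
        | {"backbone": True},
        # amide H points +z, away from the arm path below the stations
        atom("HN", "H", 68, "ASP", (1.8, 14, 0.2), hydrogen=True, parent="N"),
        atom("OH", "O", 70, "TYR", (0, 20, 0), donor=True, acceptor=True),
        atom("HH", "H", 70, "TYR", (1, 20, 0), hydrogen=True, parent="OH"),
        atom("O", "O", 35, "LEU", (0, 26, 0), acceptor=True)
        | {"backbone": True},
        atom("N", "N", 35, "LEU", (1.8, 26, -0.8), donor=True)
        | {"backbone": True},
        atom("HN", "H", 35, "LEU", (1.8, 26, 0.2), hydrogen=True, parent="N"),
        # off-axis neighbors of the protected site
        atom("N", "N", 66, "ALA", (6, 4, 0), donor=True) | {"backbone": True},
        atom("HN", "H", 66, "ALA", (7, 4, 0), hydrogen=True, parent="N"),
        atom("O", "O", 66, "ALA", (6, 4, -1.5), acceptor=True)
        | {"backbone": True},
    ]
    atoms.extend(_his_ring())
    return atoms


# arm layouts per state; H17/H6 on the hallmark donor are filled in along
# the donor->acceptor axis at generation time
def _arm_coords(state: str) -> dict[str, np.ndarray]:
    def chain(ys: float, donor: str) -> dict[str, np.ndarray]:
        """Arm hanging below a station at (0, ys, 0); `donor` is bonded."""
        other = "N6" if donor == "N17" else "N17"
        coords = {
            donor: np.array([0.0, ys - _BOND_LENGTH, 0.0]),
            "C1": np.array([0.0, ys - 3.0, -1.4]),
            other: np.array([0.0, ys - 3.55, -2.8]),
            f"H{other[1:]}": np.array([0.0, ys - 3.55, -3.8]),
            "S15": np.array([0.0, ys - 6.0, -4.2]),
            "S121": np.array([0.0, ys - 1.0, -4.8]),
        }
        return coords

    if state == "I":
        # N17 2.75 Å from Glu-12 OE1 and 2.77 Å from COM(Glu-12, Glu-14);
        # S15 within π–sulfur range of the His-13 ring centroid
        return {
            # y = sqrt(2.75^2 - 0.75^2): exactly 2.75 Å from Glu-12 OE1
            "N17": np.array([0.75, np.sqrt(7.0), 0.0]),
            "C1": np.array([0.75, 3.0, 1.0]),
            "N6": np.array([0.75, 3.5, 2.0]),
            "H6": np.array([0.75, 4.5, 2.0]),
            "S15": np.array([0.75, 1.5, 4.5]),
            "S121": np.array([0.75, 4.5, 4.5]),
        }
    if state == "II":
        return chain(8.0, "N17")
    if state == "III":
        return chain(14.0, "N17")
    if state == "IV":
        return chain(20.0, "N17")
    if state == "V":
        return chain(26.0, "N6")
    if state == "released":
        return {
            "N17": np.array([0.0, 40.0, -2.8]),
            "H17": np.array([0.0, 40.0, -3.8]),
            "C1": np.array([0.0, 40.3, -1.4]),
            "N6": np.array([0.0, 41.0, 0.0]),
            "H6": np.array([0.0, 42.0, 0.0]),
            "S15": np.array([0.0, 38.0, -4.2]),
            "S121": np.array([0.0, 42.0, -4.8]),
        }
    raise ScheduleError(f"no arm layout for state {state!r}")


@dataclass
class ToyComplexSpec:
    """Noise/flicker settings plus the frozen toy geometry."""

    noise_sigma: float = 0.05        # Å, per coordinate per frame
    flicker_probability: float = 0.02

    _topology: Topology = field(init=False, repr=False)
    _cavity_xyz: np.ndarray = field(init=False, repr=False)
    _arm_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")
        if not 0 <= self.flicker_probability < 1:
            raise ParameterError("flicker_probability must be in [0, 1)")
        cavity = _cavity_atoms()
        arm_names = ["N17", "H17", "C1", "N6", "H6", "S15", "S121"]
        arm_meta = {
            "N17": {"element": "N", "charge": 1, "donor": True},
            "H17": {"element": "H", "hydrogen": True, "parent": "N17"},
            "C1": {"element": "C"},
            "N6": {"element": "N", "charge": 1, "donor": True},
            "H6": {"element": "H", "hydrogen": True, "parent": "N6"},
            "S15": {"element": "S", "acceptor": True},
            "S121": {"element": "S", "acceptor": True},
        }
        atoms = list(cavity)
        for name in arm_names:
            atoms.append({"name": name, "res_id": 1, "res_name": "LPA",
                          "chain_id": "L", "xyz": np.zeros(3)}
                         | arm_meta[name])
        # resolve hydrogen parents to indices
        index = {}
        for i, a in enumerate(atoms):
            index[(a["chain_id"], a["res_id"], a["name"])] = i
        for a in atoms:
            if a.get("parent"):
                a["hydrogen_donor"] = index[
                    (a["chain_id"], a["res_id"], a["parent"])]
        self._topology = Topology.from_atoms(atoms)
        self._cavity_xyz = np.array([a["xyz"] for a in cavity])
        self._arm_index = {name: index[("L", 1, name)] for name in arm_names}
        self.verify_margins()

    @property
    def topology(self) -> Topology:
        return self._topology

    @property
    def n_atoms(self) -> int:
        return self._topology.n_atoms

    @property
    def arm_indices(self) -> np.ndarray:
        return np.array(sorted(self._arm_index.values()))

    @property
    def cavity_indices(self) -> np.ndarray:
        return np.arange(len(self._cavity_xyz))

    def hallmark_indices(self, state: str):
        """(donor, hydrogen, acceptor) atom indices of a state's hallmark."""
        if state not in HALLMARKS:
            return None
        donor_name, (res_name, res_id), acc_name = HALLMARKS[state]
        top = self._topology
        donor = self._arm_index[donor_name]
        hydrogen = self._arm_index[f"H{donor_name[1:]}"]
        acc = int(top.select(name=acc_name, res_name=res_name,
                             res_id=res_id)[0])
        return donor, hydrogen, acc

    def base_coords(self, state: str) -> np.ndarray:
        """Noise-free coordinates (n_atoms, 3) realizing one state."""
        coords = np.zeros((self.n_atoms, 3))
        coords[:len(self._cavity_xyz)] = self._cavity_xyz
        arm = dict(_arm_coords(state))
        hallmark = self.hallmark_indices(state)
        if hallmark is not None:
            donor_name = HALLMARKS[state][0]
            acc_xyz = self._cavity_xyz[hallmark[2]]
            d_xyz = arm[donor_name]
            unit = (acc_xyz - d_xyz) / np.linalg.norm(acc_xyz - d_xyz)
            arm[f"H{donor_name[1:]}"] = d_xyz + _DH_LENGTH * unit
            # free hydrogen on the other nitrogen points away from the path
            other = "N6" if donor_name == "N17" else "N17"
            h_other = f"H{other[1:]}"
            if h_other not in arm:
                arm[h_other] = arm[other] + np.array([0.0, 1.0, 0.0])
        for name, xyz in arm.items():
            coords[self._arm_index[name]] = xyz
        return coords

    # -- construction-time self-check ----------------------------------------

    def verify_margins(self) -> None:
        """Brute-force every donor–H–acceptor triple of every noiseless state
        layout: the hallmark must satisfy the criteria comfortably, every
        other arm↔cavity pair must violate them by the safety margin."""
        top = self._topology
        h_idx = np.flatnonzero(top.is_hydrogen)
        d_idx = top.hydrogen_donor[h_idx]
        a_idx = np.flatnonzero(top.is_acceptor)
        arm = set(self.arm_indices.tolist())
        for state in list(HALLMARKS) + ["released"]:
            coords = self.base_coords(state)
            hallmark = self.hallmark_indices(state)
            for h, d in zip(h_idx, d_idx):
                if not top.is_donor[d]:
                    continue
                for a in a_idx:
                    if a == d or ((d in arm) == (a in arm)):
                        continue  # same side: not an arm-cavity candidate
                    dist = float(np.linalg.norm(coords[a] - coords[d]))
                    dh = coords[h] - coords[d]
                    da = coords[a] - coords[d]
                    cosang = np.dot(dh, da) / (
                        np.linalg.norm(dh) * np.linalg.norm(da))
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                    is_hallmark = (hallmark is not None
                                   and (int(d), int(h), int(a)) == hallmark)
                    if is_hallmark:
                        if not (abs(dist - _BOND_LENGTH) < 1e-9 and ang < 1e-6):
                            raise TopologyError(
                                f"state {state}: hallmark geometry broken "
                                f"(d={dist:.3f} Å, angle={ang:.1f}°)")
                    elif dist < _R_CUT + _R_MARGIN and ang < _ANG_CUT + _ANG_MARGIN:
                        raise TopologyError(
                            f"state {state}: non-hallmark pair "
                            f"{top.names[d]}({top.res_names[d]}-{top.res_ids[d]})"
                            f" -> {top.names[a]}({top.res_names[a]}-"
                            f"{top.res_ids[a]}) inside margins "
                            f"(d={dist:.2f} Å, angle={ang:.1f}°)")


def default_toy_complex() -> ToyComplexSpec:
    return ToyComplexSpec()


def generate_release_trajectory(schedule: StateSchedule,
                                spec: ToyComplexSpec | None = None,
                                frame_dt: float = 0.1, seed: int = 0,
                                duration_ns: float | None = None,
                                return_details: bool = False):
    """Trajectory realizing a planted state schedule, frame by frame.

    Frames are at t = 0, frame_dt, 2·frame_dt, ...; each gets the noiseless
    layout of its scheduled state, then hallmark flicker (with the spec's
    probability, the donor is displaced to 4.0 Å along the bond axis), then
    Gaussian coordinate noise.  Deterministic under a fixed seed.

    With ``return_details=True`` also returns a dict with the planted
    per-frame state names and the flicker mask, for recovery checks.
    """
    if spec is None:
        spec = default_toy_complex()
    if frame_dt <= 0:
        raise ParameterError("frame_dt must be positive")
    total = schedule.total_ns if duration_ns is None else duration_ns
    if schedule.total_ns > total + 1e-9:
        raise ScheduleError(
            f"schedule extends to {schedule.total_ns} ns but the trajectory "
            f"covers only {total} ns")
    n_frames = int(round(total / frame_dt))
    times = frame_dt * np.arange(n_frames)

    rng = np.random.default_rng(seed)
    base = {state: spec.base_coords(state)
            for state in list(HALLMARKS) + ["released"]}
    planted = [schedule.state_at(float(t)) for t in times]
    flicker = rng.random(n_frames) < spec.flicker_probability
    coords = np.empty((n_frames, spec.n_atoms, 3))
    for f, state in enumerate(planted):
        frame = base[state].copy()
        hallmark = spec.hallmark_indices(state)
        if hallmark is None:
            flicker[f] = False
        elif flicker[f]:
            d, h, a = hallmark
            unit = frame[d] - frame[a]
            unit /= np.linalg.norm(unit)
            shift = frame[a] + _FLICKER_DIST * unit - frame[d]
            frame[d] += shift
            frame[h] += shift
        coords[f] = frame
    if spec.noise_sigma > 0:
        coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    traj = Trajectory(coords=coords, times=times, topology=spec.topology)
    if return_details:
        return traj, {"planted_states": planted, "flicker": flicker,
                      "schedule": schedule}
    return traj
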