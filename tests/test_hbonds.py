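"""Hydrogen-bond detection: criterion cases, brute-force oracle equivalence,
monotonicity, charged classification, contact tables, and π–sulfur
contacts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipoarm.errors import SelectionError, TopologyError
from lipoarm.hbonds import (HBondCriteria, classify_charged, contact_table,
                            detect_hbonds, pi_sulfur_contacts)
from lipoarm.states import STATE_NAMES
from lipoarm.synthetic import (ToyComplexSpec, generate_release_trajectory,
                               variant_schedule)
from lipoarm.topology import AtomSelection, Topology
from lipoarm.trajectory import Trajectory


def brute_force_hbonds(coords, topology, criteria):
    """Independent oracle: plain triple loop over all donor/H/acceptor
    combinations."""
    found = set()
    for h in range(topology.n_atoms):
        if not topology.is_hydrogen[h]:
            continue
        d = int(topology.hydrogen_donor[h])
        if d < 0 or not topology.is_donor[d]:
            continue
        for a in range(topology.n_atoms):
            if not topology.is_acceptor[a] or a == d:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            if dist > criteria.max_da_distance:
                continue
            v1 = coords[h] - coords[d]
            v2 = coords[a] - coords[d]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang <= criteria.max_hda_angle:
                found.add((d, h, a))
    return found


class TestCriterionCases:
    def test_collinear_bond(self, simple_topology):
        top = simple_topology()
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [2.8, 0, 0]])
        records = detect_hbonds(coords, top)
        assert len(records) == 1
        rec = records[0]
        assert rec.distance == pytest.approx(2.8)
        assert rec.angle == pytest.approx(0.0, abs=1e-9)

    def test_distance_cutoff(self, simple_topology):
        top = simple_topology()
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [3.6, 0, 0]])
        assert detect_hbonds(coords, top) == []

    def test_angle_cutoff(self, simple_topology):
        top = simple_topology()
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [0, 2.8, 0]])
        assert detect_hbonds(coords, top) == []

    def test_hydrogen_without_donor_raises(self):
        top = Topology.from_atoms([
            {"name": "H", "hydrogen": True},
            {"name": "A", "acceptor": True},
            {"name": "D", "donor": True},
        ])
        with pytest.raises(TopologyError, match="no bonded donor"):
            detect_hbonds(np.zeros((3, 3)), top)


class TestOracleEquivalence:
    def test_random_frames_match_triple_loop(self, toy_spec, rng):
        """Vectorized detection equals the brute-force loop on 100 random
        perturbations of the toy geometry."""
        top = toy_spec.topology
        criteria = HBondCriteria()
        states = list("I II III IV V".split()) + ["released"]
        for trial in range(100):
            state = states[trial % len(states)]
            coords = toy_spec.base_coords(state) + rng.normal(
                scale=0.35, size=(top.n_atoms, 3))
            got = {(r.donor, r.hydrogen, r.acceptor)
                   for r in detect_hbonds(coords, top, criteria)}
            assert got == brute_force_hbonds(coords, top, criteria)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(r=st.floats(2.0, 6.0), theta=st.floats(5.0, 90.0))
    def test_loosening_criteria_never_removes_bonds(self, toy_spec, r, theta):
        rng = np.random.default_rng(99)
        top = toy_spec.topology
        coords = toy_spec.base_coords("I") + rng.normal(
            scale=0.3, size=(top.n_atoms, 3))
        tight = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(
            coords, top, HBondCriteria(r, theta))}
        loose = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(
            coords, top, HBondCriteria(r + 0.5, min(theta + 10, 90.0)))}
        assert tight <= loose


class TestChargedClassification:
    def test_charged_arm_nitrogen_donor(self, toy_spec):
        coords = toy_spec.base_coords("II")
        records = detect_hbonds(coords, toy_spec.topology)
        n17 = toy_spec.topology.index_of("N17")
        rec = next(r for r in records if r.donor == n17)
        assert classify_charged(rec, toy_spec.topology) is True

    def test_neutral_pair_not_charged(self, simple_topology):
        top = simple_topology()
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [2.8, 0, 0]])
        rec = detect_hbonds(coords, top)[0]
        assert classify_charged(rec, top) is False

    def test_residue_group_charge_toggle(self):
        """Acceptor oxygen is neutral itself, but its carboxylate group
        carries -1: charged only under the group rule."""
        top = Topology.from_atoms([
            {"name": "D", "donor": True, "res_id": 1},
            {"name": "H", "hydrogen": True, "hydrogen_donor": 0, "res_id": 1},
            {"name": "OD1", "acceptor": True, "res_id": 2, "res_name": "ASP"},
            {"name": "OD2", "res_id": 2, "res_name": "ASP", "charge": -1},
        ])
        coords = np.array([[0, 0, 0], [1, 0, 0], [2.8, 0, 0], [3.5, 1, 0.0]])
        rec = detect_hbonds(coords, top)[0]
        assert classify_charged(rec, top) is False
        assert classify_charged(rec, top, residue_charge=True) is True


class TestContactTable:
    def test_wt_state_ii_occupancy(self, wt_run, arm_cavity):
        traj, _ = wt_run
        arm, cavity = arm_cavity
        table = contact_table(traj, arm_selection=arm, cavity_selection=cavity)
        occ = table.occupancy(40.0, 240.0)
        ser = occ[(occ["arm_atom"] == "N17")
                  & (occ["cavity_res_name"] == "SER")]
        assert len(ser) == 1
        assert float(ser["occupancy"].iloc[0]) >= 0.95

    def test_occupancy_sum_rule(self, wt_run, arm_cavity):
        traj, _ = wt_run
        arm, cavity = arm_cavity
        table = contact_table(traj, arm_selection=arm, cavity_selection=cavity)
        occ = table.occupancy()
        assert ((occ["occupancy"] >= 0) & (occ["occupancy"] <= 1)).all()
        assert (occ["occupancy"] * occ["total_frames"]
                ).round().astype(int).equals(occ["bonded_frames"])

    def test_empty_cavity_selection_raises(self, wt_run):
        traj, _ = wt_run
        with pytest.raises(SelectionError):
            contact_table(traj,
                          arm_selection=AtomSelection(chain_id="L"),
                          cavity_selection=AtomSelection(chain_id="Z"))

    def test_overlapping_selections_raise(self, wt_run):
        traj, _ = wt_run
        with pytest.raises(SelectionError, match="overlap"):
            contact_table(traj, arm_selection=AtomSelection(chain_id="L"),
                          cavity_selection=AtomSelection())

    def test_released_frames_have_no_contacts(self, toy_spec):
        spec = ToyComplexSpec(noise_sigma=0.05, flicker_probability=0.0)
        traj = generate_release_trajectory(variant_schedule("WT"), spec,
                                           seed=5)
        released = traj.times >= 280.0
        sub = Trajectory(coords=traj.coords[released],
                         times=traj.times[released],
                         topology=traj.topology)
        table = contact_table(sub,
                              arm_selection=AtomSelection(chain_id="L"),
                              cavity_selection=AtomSelection(chain_id="A"))
        assert len(table.records) == 0


class TestPiSulfur:
    def test_within_and_beyond_cutoff(self, toy_spec):
        top = toy_spec.topology
        coords = toy_spec.base_coords("I")
        s15 = top.index_of("S15")
        near = pi_sulfur_contacts(coords, top, [s15], [("HIS", 13)])
        assert len(near) == 1 and near[0]["distance_A"] <= 5.5
        far = coords.copy()
        far[s15] += np.array([0, 0, -10.0])
        assert pi_sulfur_contacts(far, top, [s15], [("HIS", 13)]) == []

    def test_state_i_contact_present_with_noise(self, wt_run):
        traj, details = wt_run
        s15 = traj.topology.index_of("S15")
        first_i = int(np.flatnonzero(
            np.array(details["planted_states"]) == "I")[0])
        contacts = pi_sulfur_contacts(traj.coords[first_i], traj.topology,
                                      [s15], [("HIS", 13)])
        assert [c["ring_res_id"] for c in contacts] == [13]

    def test_missing_ring_annotation_raises(self, toy_spec):
        with pytest.raises(TopologyError, match="ring"):
            pi_sulfur_contacts(toy_spec.base_coords("I"), toy_spec.topology,
                               [toy_spec.topology.index_of("S15")],
                               [("GLU", 12)])
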