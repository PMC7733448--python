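import numpy as np
import pytest

from lipoarm.hbonds import contact_table
from lipoarm.states import label_frames, smooth_labels, step_report
from lipoarm.synthetic import (build_reference_landscape, default_toy_complex,
                               generate_release_trajectory, variant_schedule)
from lipoarm.topology import AtomSelection, Topology


@pytest.fixture(scope="session")
def toy_spec():
    return default_toy_complex()


@pytest.fixture(scope="session")
def landscape():
    return build_reference_landscape()


@pytest.fixture(scope="session")
def wt_run(toy_spec):
    """Default-noise WT trajectory with its planted details."""
    traj, details = generate_release_trajectory(
        variant_schedule("WT"), toy_spec, seed=2024, return_details=True)
    return traj, details


@pytest.fixture(scope="session")
def arm_cavity():
    return AtomSelection(chain_id="L"), AtomSelection(chain_id="A")


def run_segmentation(traj, window=11):
    """Shared contact -> labels -> smoothed -> report pipeline."""
    table = contact_table(traj,
                          arm_selection=AtomSelection(chain_id="L"),
                          cavity_selection=AtomSelection(chain_id="A"))
    raw = label_frames(table, topology=traj.topology)
    smoothed = smooth_labels(raw, window)
    return table, raw, smoothed, step_report(smoothed)


@pytest.fixture
def simple_topology():
    """Three-atom donor/hydrogen/acceptor system for criterion tests."""
    def build(coords_extra=()):
        atoms = [
            {"name": "D", "element": "N", "res_id": 1, "res_name": "AAA",
             "donor": True},
            {"name": "H", "element": "H", "res_id": 1, "res_name": "AAA",
             "hydrogen": True, "hydrogen_donor": 0},
            {"name": "A", "element": "O", "res_id": 2, "res_name": "BBB",
             "acceptor": True},
        ]
        atoms.extend(coords_extra)
        return Topology.from_atoms(atoms)
    return build


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
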