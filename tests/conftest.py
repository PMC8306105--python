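import numpy as np
import pytest

from cgdock import System, generate_restraints, project_to_lattice
from cgdock.fixtures import ToyComplexSpec, make_toy_complex
from cgdock.sampler import SimState


@pytest.fixture(scope="session")
def toy():
    """Small reference complex: helix receptor + helix ligand in contact."""
    return make_toy_complex(ToyComplexSpec(seed=1))


@pytest.fixture(scope="session")
def toy_chains(toy):
    rec = project_to_lattice(toy.rec_input, toy.rec_seq, role="receptor")
    lig = project_to_lattice(toy.lig_input, toy.lig_seq, role="ligand")
    return rec, lig


@pytest.fixture()
def docked_state(toy, toy_chains):
    """A two-chain simulation state with default two-tier restraints."""
    from cgdock.protocol import generate_starting_structures

    rec, lig = toy_chains
    systems = generate_starting_structures(rec, lig, 1, offset=12.0,
                                           rng=np.random.default_rng(7))
    rsets = [
        generate_restraints(toy.rec_input, molecule="receptor"),
        generate_restraints(toy.lig_input, molecule="ligand", weight_scale=0.1),
    ]
    return SimState(systems[0], rsets=rsets), rsets


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
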