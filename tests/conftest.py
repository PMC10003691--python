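import numpy as np
import pytest

from xlassembly.synth import (DEFAULT_PLANTED_TRANSFORM, SynthSpec,
                              generate_decoy_poses, make_toy_assembly,
                              make_toy_chain, plant_pose_and_links)


@pytest.fixture(scope="session")
def receptor_trimer():
    return make_toy_assembly(SynthSpec(seed=0, n_chains=3))


@pytest.fixture(scope="session")
def ligand_dimer():
    return make_toy_assembly(SynthSpec(seed=1, n_chains=2))


@pytest.fixture(scope="session")
def planted_fixture(receptor_trimer, ligand_dimer):
    """(pose, links) with 5 geometrically consistent + 2 false DSBU links."""
    return plant_pose_and_links(receptor_trimer, ligand_dimer,
                                DEFAULT_PLANTED_TRANSFORM,
                                n_true=5, n_false=2, seed=0)


@pytest.fixture(scope="session")
def decoy_poses(receptor_trimer, ligand_dimer, planted_fixture):
    pose, links = planted_fixture
    return generate_decoy_poses(receptor_trimer, ligand_dimer, 20,
                                min_displacement=50.0, seed=0,
                                reference=pose.transform, links=links)


@pytest.fixture(scope="session")
def helix_chain_30():
    """A single 30-residue helical toy chain (N, CA, C, O backbone)."""
    return make_toy_chain(SynthSpec(seed=0, chain_length=30))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
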