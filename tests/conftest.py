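"""Shared fixtures: synthetic structures planted at reference geometries.

All co-crystal-like fixtures are synthetic: they are built by the package's
generator so that the descriptor pipeline can be exercised against known
ground truth without any structure download.
"""

import numpy as np
import pytest

from rafdimer.synthetic_data import SyntheticSpec, make_structure


@pytest.fixture(scope="session")
def phi_dimer():
    """Synthetic stand-in for a PHI1-bound dimer: αC 19.1/19.0 Å, DFG-out,
    locked Lys483–Glu501 salt bridge, ligand h-bonded to Glu501."""
    spec = SyntheticSpec(
        n_protomers=2,
        alpha_c_target=[19.1, 19.0],
        dfg_target=290.0,
        ke_target=2.8,
        ligand_present=True,
        ligand_resname="PHI",
        ligand_glu501_hbond=True,
        asp594_mode="accepts",
        his574_hbond=True,
    )
    return make_structure(spec)


@pytest.fixture(scope="session")
def vem_dimer():
    """Synthetic stand-in for a vemurafenib-bound dimer: αC-out, DFG-in,
    no ligand–Glu501 h-bond, sulfonamide donating to the Asp594 backbone."""
    spec = SyntheticSpec(
        n_protomers=2,
        alpha_c_target=[22.5, 22.7],
        dfg_target=100.0,
        ke_target=5.2,
        ligand_present=True,
        ligand_resname="VEM",
        ligand_glu501_hbond=False,
        asp594_mode="donates",
        his574_hbond=False,
    )
    return make_structure(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_rigid_transform(rng):
    """A uniformly random rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-50.0, 50.0, size=3)
    return rot, trans


def apply_rigid(structure, rot, trans):
    coords = structure.coordinates() @ rot.T + trans
    return structure.with_coordinates(coords)
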