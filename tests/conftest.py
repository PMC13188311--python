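import numpy as np
import pytest
from hypothesis import settings
from rdkit import Chem
from rdkit.Chem import AllChem

from tabscount.fixtures import fig2_system
from tabscount.pipeline import analyze_molecule

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fig2():
    """Two equivalent 3-state torsions with the bit swap: |S|=9, nTABS=6."""
    return fig2_system()


def dihedral_coords(theta_deg: float) -> np.ndarray:
    """Four-atom chain a-b-c-d built so the a-b-c-d dihedral equals theta.

    b and c sit on the x axis; a points along +y at b; the perpendicular
    component of d at c is +y rotated by theta about the b->c axis
    (right-hand rule), which is exactly the IUPAC signed dihedral.
    """
    theta = np.radians(theta_deg)
    return np.array(
        [
            [-0.5, 1.0, 0.0],
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [2.0, np.cos(theta), np.sin(theta)],
        ]
    )


def embed_conformers(smiles: str, n_confs: int, seed: int = 0xC0FFEE % 2**31):
    """Heavy-atom molecule with 3D conformers (hydrogens used for
    embedding, then stripped; coordinates are kept)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    return Chem.RemoveHs(mol)


@pytest.fixture(scope="session")
def diphenylethane():
    """Analyzed 1,2-diphenylethane: 3 bits, bit group of order 2."""
    return analyze_molecule("c1ccccc1CCc1ccccc1")


@pytest.fixture(scope="session")
def diphenylethane_confs():
    return embed_conformers("c1ccccc1CCc1ccccc1", n_confs=20)
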