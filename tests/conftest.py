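import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from rdkit import Chem
from rdkit.Chem import AllChem

import torsionprofiles as tp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library() -> tp.TorsionLibrary:
    return tp.fixture_library()


@pytest.fixture(scope="session")
def toy_molecules():
    return tp.make_toy_molecules()


@pytest.fixture(scope="session")
def embedded_diene() -> tp.MoleculeRecord:
    """The permethylated diene toy molecule with one embedded 3D conformer."""
    mol = Chem.AddHs(Chem.MolFromSmiles("CC(C)=C(C)C(C)=C"))
    params = AllChem.ETKDGv3()
    params.randomSeed = 20240901
    AllChem.EmbedMolecule(mol, params)
    records, _ = tp.curate_molecule(mol, "diene_toy")
    assert len(records) == 1
    return records[0]


@pytest.fixture(scope="session")
def two_peak_params() -> tp.FitParameters:
    return tp.FitParameters([(1.0, np.radians(60.0), 0.35), (0.6, np.radians(160.0), 0.30)])
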