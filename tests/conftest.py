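import numpy as np
import pytest

from adrnet.data import SyntheticSpec, generate_synthetic
from adrnet.featurize import Molecule, featurize_batch

# a spread of drug-like SMILES used by featurization property tests
DRUG_LIKE_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
    "CC(=O)Nc1ccc(O)cc1",  # paracetamol
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",  # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",  # ibuprofen
    "c1ccc2c(c1)cccn2",  # quinoline
    "C1CCNCC1",
    "CC(N)Cc1ccccc1",
    "OCC(O)CO",
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",  # melatonin
    "Clc1ccccc1Cl",
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",  # atenolol
    "N[C@@H](C)C(=O)O",  # L-alanine
    "CN(C)CCC=C1c2ccccc2CCc2ccccc21",  # amitriptyline
    "O=C(O)c1ccccc1O",
    "C(F)(F)F",
    "CCS",
    "c1ccsc1",
    "O=[N+]([O-])c1ccccc1",
    "C#N",
    "CC1=CC(=O)C=CC1=O",
    "C1CCOC1",
    "CCCCCCCCCC",
    "CC(C)(C)c1ccccc1",
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",  # citric acid
    "NCCc1ccc(O)c(O)c1",  # dopamine
]


@pytest.fixture(scope="session")
def drug_like_smiles():
    return list(DRUG_LIKE_SMILES)


@pytest.fixture(scope="session")
def small_synthetic_dataset():
    """40 planted-rule molecules with 4 labels, zero noise."""
    spec = SyntheticSpec(n_molecules=40, n_labels=4, label_noise=0.0, seed=7)
    records = generate_synthetic(spec)
    return spec, records


@pytest.fixture(scope="session")
def small_featurized(small_synthetic_dataset):
    """Featurized version of the small synthetic dataset (one obabel call)."""
    _, records = small_synthetic_dataset
    result = featurize_batch(
        [Molecule(r.id, r.smiles) for r in records], on_error="strict"
    )
    labels = np.array([r.labels for r in records], dtype=float)
    return result.pairs, labels
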