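import numpy as np
import pytest

from spikescreen.chem_encode import FingerprintDataset
from spikescreen.synthetic_data import SyntheticSpec, generate
from spikescreen.train_eval import SearchGrid


@pytest.fixture
def smiles_csv(tmp_path):
    """Three valid molecules with binary labels, MoleculeNet layout."""
    p = tmp_path / "mols.csv"
    p.write_text("smiles,label\nCCO,0\nc1ccccc1,1\nCC(=O)O,1\n")
    return p


@pytest.fixture
def easy_dataset():
    """Small, clearly separable synthetic fingerprint dataset."""
    return generate(
        SyntheticSpec(
            n_per_class=(120, 120),
            n_bits=64,
            n_informative=16,
            p_on_active=0.8,
            p_background=0.05,
            seed=42,
        )
    )


@pytest.fixture
def tiny_grid():
    """One-point grid that trains in well under a second."""
    return SearchGrid(
        n_hidden=(32,),
        beta=(0.9,),
        slope=(50.0,),
        optimizer=("Adamax",),
        lr=(2e-3,),
        wd=(0.0,),
        gc=(False,),
        epochs=(3,),
    )


@pytest.fixture
def square_dataset():
    """Deterministic 4-sample dataset for exact bookkeeping checks."""
    bits = np.array(
        [[1, 1, 0, 0], [0, 1, 1, 0], [1, 1, 1, 0], [0, 0, 0, 1]], dtype=np.int8
    )
    return FingerprintDataset(bits, np.array([0, 0, 1, 1]))
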