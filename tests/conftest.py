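import numpy as np
import pandas as pd
import pytest

from rulefinder.dataset import Dataset, ModifierRecord, binarize_by_median
from rulefinder.synthetic import SyntheticSpec, generate_library


def make_records(yields, smiles=None, **overrides):
    """Small labeled-free dataset with deterministic filler features."""
    n = len(yields)
    smiles = smiles or ["CC(=O)O"] * n
    records = []
    for i in range(n):
        records.append(
            ModifierRecord(
                id=f"m{i}",
                smiles=smiles[i],
                yield_percent=float(yields[i]),
                fe_loading=1.0 + 0.1 * i,
                modifier_sbu=0.5,
                fe_hf=0.2,
                **overrides,
            )
        )
    return Dataset(tuple(records))


@pytest.fixture
def toy_dataset():
    return make_records([10.0, 20.0, 30.0, 40.0])


@pytest.fixture(scope="session")
def library_molecules():
    """36 distinct synthetic modifier SMILES (benzoates, aliphatic, amino acids)."""
    return [smi for _, smi, _ in generate_library(SyntheticSpec(), seed=1)]


@pytest.fixture(scope="session")
def labeled_synthetic():
    from rulefinder.synthetic import generate_dataset

    ds, truth = generate_dataset(SyntheticSpec(), seed=0)
    return ds, truth


def balanced_labels(n):
    return np.array(["high", "low"] * (n // 2))


def write_dataset_csv(path, rows):
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
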