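from pathlib import Path

import numpy as np
import pytest
from rdkit import RDLogger

import hybridqsar as hq

RDLogger.DisableLog("rdApp.*")

DATA_DIR = Path(__file__).parent / "data"

# small panel spanning rings, heteroatoms, chirality and acyclic molecules
PANEL_SMILES = [
    "CCO", "c1ccccc1", "c1ccncc1", "C[C@H](N)C(=O)O", "C",
    "CC(=O)Oc1ccccc1C(=O)O", "c1ccc2ccccc2c1", "C1CCCCC1", "CC(C)CC",
    "c1ccsc1", "c1ccoc1", "CC(=O)NC", "FC(F)(F)c1ccccc1", "CCOCC",
    "OC(=O)c1ccncc1", "CC(C)(C)O", "BrCCBr", "CNC", "C1CCNCC1",
    "N#Cc1ccccc1", "CC(N)=O", "Clc1ccc(Cl)cc1", "CCS", "OCC(O)CO",
    "c1cnc2ccccc2c1",
]


@pytest.fixture(scope="session")
def vocab():
    return hq.build_vocab()


@pytest.fixture(scope="session")
def panel():
    return list(PANEL_SMILES)


@pytest.fixture(scope="session")
def golden_raw_path():
    return DATA_DIR / "golden_raw.csv"


@pytest.fixture(scope="session")
def small_model(vocab):
    """A small-but-complete model for fast structural tests."""
    cfg = hq.ModelConfig(vocab_size=len(vocab), seed=1, gat_hidden=16,
                         atom_embed_dim=8, desc_dims=(544, 16, 8),
                         head_hidden=6)
    return hq.HybridIC50Model(cfg)


@pytest.fixture()
def tiny_clean_dataset():
    """32 clean single-target samples with a noiseless planted signal."""
    spec = hq.FixtureSpec(n_molecules=32, n_targets=1,
                          target_size_ratios=(1.0,), noise_sd=0.0,
                          dirty_fraction=0.0, duplicate_fraction=0.0,
                          seed=11)
    df = hq.generate_activity_table(spec)
    records = [
        hq.ActivityRecord(r.smiles, r.target_chembl_id, r.standard_value,
                          r.standard_units, r.standard_type)
        for r in df.itertuples()
    ]
    return hq.clean_activities(records)


def records_from_frame(df):
    return [
        hq.ActivityRecord(r.smiles, r.target_chembl_id, r.standard_value,
                          r.standard_units, r.standard_type)
        for r in df.itertuples()
    ]
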