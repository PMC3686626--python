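import logging

import pytest
from rdkit import RDLogger

import fpbench as fb

RDLogger.DisableLog("rdApp.*")
logging.getLogger("fpbench").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def chembl_like_target():
    """Small ChEMBL-style target: 20 actives in 8 series, 40 matched decoys,
    5 repetitions with 3 queries each."""
    recipe = fb.FixtureRecipe("ChEMBL-like", n_actives=20, n_decoys=40,
                              n_series=8, difficulty=0.5, seed=7,
                              repetitions=5, n_queries=3)
    return fb.generate_target(recipe, "T1")


@pytest.fixture(scope="session")
def dud_like_target():
    recipe = fb.FixtureRecipe("DUD-like", n_actives=15, n_decoys=60,
                              n_series=5, difficulty=0.3, seed=3,
                              repetitions=4, n_queries=3)
    return fb.generate_target(recipe, "T2")


@pytest.fixture(scope="session")
def fixture_smiles():
    """A handful of drug-like molecules for fingerprint-level checks."""
    return [
        "c1ccccc1", "Cc1ccccc1", "c1ccc(-c2ccccc2)cc1", "CCO", "CCN(CC)CC",
        "c1ccc2[nH]ccc2c1", "CC(=O)Oc1ccccc1C(=O)O", "c1ccncc1",
        "O=C(N)c1ccccc1", "Clc1ccc(CN2CCOCC2)cc1",
    ]
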