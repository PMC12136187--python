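"""Shared fixtures: small drug-like SMILES sets and synthetic data."""

from __future__ import annotations

import numpy as np
import pytest

from fpgan.dataset import make_synthetic_fpset, make_synthetic_library

# twenty well-known drug-like molecules spanning sizes and functional groups
DRUGLIKE_SMILES = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("naproxen", "COc1ccc2cc(C(C)C(=O)O)ccc2c1"),
    ("diazepam", "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21"),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("nicotine", "CN1CCCC1c1cccnc1"),
    ("procaine", "CCN(CC)CCOC(=O)c1ccc(N)cc1"),
    ("lidocaine", "CCN(CC)CC(=O)Nc1c(C)cccc1C"),
    ("metformin", "CN(C)C(=N)NC(=N)N"),
    ("salbutamol", "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1"),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("cimetidine", "CC1=C(CSCCNC(=NC)NC#N)N=CN1"),
    ("fluoxetine", "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1"),
    ("sulfanilamide", "Nc1ccc(S(N)(=O)=O)cc1"),
    ("benzocaine", "CCOC(=O)c1ccc(N)cc1"),
    ("phenytoin", "O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1"),
    ("chlorpromazine", "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21"),
]


@pytest.fixture(scope="session")
def druglike_smiles() -> list[tuple[str, str]]:
    return DRUGLIKE_SMILES


@pytest.fixture(scope="session")
def small_fpset():
    """600-row separable fingerprint set for quick classifier tests."""
    return make_synthetic_fpset(n_active=300, n_inactive=300, seed=11)


@pytest.fixture(scope="session")
def default_fpset():
    """The default-condition fingerprint set (2,000 per class)."""
    return make_synthetic_fpset(seed=0)


@pytest.fixture(scope="session")
def planted_library():
    """1,000-molecule toy library with ~30% planted pyrazole-amide cores."""
    records, truth = make_synthetic_library(n=1000, fraction_with_core=0.3,
                                            seed=5)
    return records, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
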