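"""Shared fixtures: small 3D molecules and a synthetic aligned set.

Everything is generated programmatically at test time; no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from comsia.app import FixtureSpec, generate_fixture
from comsia.chemio import Molecule, MoleculeSet, annotate_atoms
from comsia.fields import FieldConfig, compute_all_fields
from comsia.grid import build_grid
from comsia.preprocess import build_feature_matrix


def mol3d(smiles: str, name: str, activity: float | None = None, seed: int = 7) -> Molecule:
    """Embed a SMILES in 3D (fixed seed) and wrap it as a Molecule."""
    rdmol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    assert AllChem.EmbedMolecule(rdmol, randomSeed=seed) == 0
    AllChem.UFFOptimizeMolecule(rdmol)
    rdmol.SetProp("_Name", name)
    return Molecule(name=name, rdmol=rdmol, activity=activity)


@pytest.fixture(scope="session")
def water():
    return annotate_atoms(mol3d("O", "water"))


@pytest.fixture(scope="session")
def methane():
    return annotate_atoms(mol3d("C", "methane"))


@pytest.fixture(scope="session")
def formaldehyde():
    return annotate_atoms(mol3d("C=O", "formaldehyde"))


@pytest.fixture(scope="session")
def ethanol():
    return annotate_atoms(mol3d("CCO", "ethanol"))


@pytest.fixture(scope="session")
def dimethyl_ether():
    return annotate_atoms(mol3d("COC", "dimethyl_ether"))


@pytest.fixture(scope="session")
def butane():
    return annotate_atoms(mol3d("CCCC", "butane"))


@pytest.fixture(scope="session")
def small_fixture():
    """10 train + 3 test aligned molecules with planted activities (seed 1)."""
    return generate_fixture(FixtureSpec(n_train=10, n_test=3, seed=1, noise_sd=0.1))


@pytest.fixture(scope="session")
def small_feature_matrix(small_fixture):
    """Feature matrix over the small fixture (train + test rows)."""
    train, test, _ = small_fixture
    grid = build_grid([train, test])
    cfg = FieldConfig()
    tt = compute_all_fields(train, grid, cfg)
    te = compute_all_fields(test, grid, cfg)
    fm = build_feature_matrix(
        tt, te, activities=list(train.activities) + list(test.activities)
    )
    return fm, grid
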