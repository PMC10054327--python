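"""Shared fixtures: synthetic structures, profiles, and fast model grids."""

from __future__ import annotations

import numpy as np
import pytest

from hypercys import synthetic
from hypercys.sequence import PSSMProfile
from hypercys.structure import find_cysteines

#: Tiny single-candidate hyperparameter grids so model tests exercise the
#: full training protocol without the cost of the default search space.
FAST_GRIDS = {
    "KNN": {"clf__n_neighbors": [5]},
    "LR": {"clf__C": [1]},
    "SVM": {"clf__estimator__C": [1], "clf__estimator__gamma": ["scale"]},
    "LGBM": {"clf__num_leaves": [15], "clf__n_estimators": [50]},
    "RF": {"clf__n_estimators": [100]},
    "MLP": {"clf__hidden_layer_sizes": [(16,)], "clf__max_iter": [300]},
}

HELIX_SEQUENCE = "MKACDEFGHIKLMNPQRSTVWYC"


@pytest.fixture(scope="session")
def helix():
    structure, pdb_text = synthetic.make_helix_peptide(HELIX_SEQUENCE, seed=1)
    return structure, pdb_text


@pytest.fixture(scope="session")
def helix_sites(helix):
    structure, _ = helix
    return find_cysteines(structure)


@pytest.fixture(scope="session")
def helix_pssm(helix):
    structure, _ = helix
    profile, text = synthetic.synth_pssm(structure.chains["A"], seed=2)
    return profile, text


@pytest.fixture(scope="session")
def helix_reports(helix):
    structure, _ = helix
    return synthetic.fabricate_reports(structure, seed=3)


@pytest.fixture
def random_pssm():
    def _make(L: int = 8, seed: int = 0) -> PSSMProfile:
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
        return PSSMProfile(sequence=seq, matrix=rng.integers(-8, 9, size=(L, 20)))

    return _make
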