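import numpy as np
import pytest

from cbscreen.chemio import Molecule, embed_conformers
from cbscreen.features import perceive_features
from cbscreen.model import PharmacophoreModel
from cbscreen.synthetic import make_feature_benchmark, make_random_model


@pytest.fixture(scope="session")
def benzene_ens():
    return embed_conformers(Molecule.from_smiles("c1ccccc1", "benzene"), seed=11)


@pytest.fixture(scope="session")
def methanol_ens():
    return embed_conformers(Molecule.from_smiles("CO", "methanol"), seed=11)


@pytest.fixture(scope="session")
def pyridine_ens():
    return embed_conformers(Molecule.from_smiles("c1ccncc1", "pyridine"), seed=11)


@pytest.fixture(scope="session")
def benzene_features(benzene_ens):
    return perceive_features(benzene_ens)


@pytest.fixture(scope="session")
def bench_model() -> PharmacophoreModel:
    return make_random_model(seed=101)


@pytest.fixture(scope="session")
def small_benchmark(bench_model):
    """Noise-free planted benchmark shared by matcher/enrichment tests."""
    return make_feature_benchmark(bench_model, n_act=15, n_dec=40, noise_sd=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
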