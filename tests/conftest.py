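import numpy as np
import pytest

import molmpn as m


@pytest.fixture(scope="session")
def fixture_smiles() -> list[str]:
    """Ten deterministic small molecules from the fragment grammar."""
    return m.generate_molecules(m.FixtureConfig(n=10, seed=42))


@pytest.fixture(scope="session")
def fixture_graphs(fixture_smiles):
    return [m.mol_to_graph(s) for s in fixture_smiles]


@pytest.fixture(scope="session")
def small_records() -> list[m.DatasetRecord]:
    """~90 unique labelled molecules, enough to train a toy model quickly."""
    recs = m.make_records(m.FixtureConfig(n=120, seed=5, noise_sd=0.05))
    return m.clean_dataset(recs)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
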