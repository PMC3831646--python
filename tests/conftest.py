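import numpy as np
import pytest

from cladeprimer.simulate import SyntheticDbSpec, generate_database


@pytest.fixture(scope="session")
def small_spec():
    """A compact planted-signature database spec shared across tests."""
    return SyntheticDbSpec(
        seed=11,
        n_phyla=2,
        genera_per_phylum=2,
        seqs_per_genus=3,
        seq_length=900,
    )


@pytest.fixture(scope="session")
def small_db(small_spec):
    db, truth = generate_database(small_spec)
    return db, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
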