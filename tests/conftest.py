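import numpy as np
import pytest

from selsvm.screening import train_two_step
from selsvm.synthetic import SyntheticSpec, generate_corpus


SMALL_SPEC = SyntheticSpec(
    n_subtypes=3,
    n_ligand=60,
    n_selective=12,
    n_multi=12,
    n_background=300,
    n_families=60,
    n_known_nonligand=15,
    seed=7,
)


@pytest.fixture(scope="session")
def small_corpus():
    """A compact synthetic three-subtype corpus shared across tests."""
    return generate_corpus(SMALL_SPEC)


@pytest.fixture(scope="session")
def training_fingerprints(small_corpus):
    """Fingerprints restricted to training compounds plus the screening
    background — the clustering input for putative-negative generation."""
    ids = [r.compound_id for r in small_corpus.training_records]
    ids += small_corpus.ids_with_role("background")
    return small_corpus.fingerprints.subset(ids)


@pytest.fixture(scope="session")
def trained_model(small_corpus, training_fingerprints):
    """A two-step model trained on the compact corpus."""
    return train_two_step(
        small_corpus.training_records,
        small_corpus.descriptors,
        training_fingerprints,
        small_corpus.targets,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
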