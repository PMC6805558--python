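import pytest

from medrqe.classifier import PairFeaturizer, train_lr
from medrqe.fixtures import (
    FixtureSpec,
    fixture_pos_lexicon,
    generate_collection,
    generate_rqe_pairs,
)
from medrqe.qtypes import load_default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return load_default_taxonomy()


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def collection(fixture_spec, taxonomy):
    return generate_collection(fixture_spec, taxonomy)


@pytest.fixture(scope="session")
def pos_lexicon(taxonomy, collection):
    return fixture_pos_lexicon(taxonomy, collection)


@pytest.fixture(scope="session")
def featurizer(taxonomy, pos_lexicon):
    return PairFeaturizer(taxonomy=taxonomy, pos_lexicon=pos_lexicon)


@pytest.fixture(scope="session")
def trained_model(collection, fixture_spec, taxonomy, featurizer):
    """A model trained on 1,000 fixture pairs, shared across tests."""
    pairs = generate_rqe_pairs(collection, fixture_spec, taxonomy, n_pairs=1000)
    return train_lr(pairs, seed=7, featurizer=featurizer)
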