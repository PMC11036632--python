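import pytest

from picostruct.backends import TrainingConfig, train_extractive, train_generative
from picostruct.grammar import build_grammar
from picostruct.schema import default_schema
from picostruct.synth import FixtureConfig, generate_corpus

# Desk-scale study conditions: 200 training / 50 held-out synthetic
# documents, d = 32 backends, fixed seeds.
TRAIN_SEED = 11
TEST_SEED = 12
RUN_SEED = 7
N_TRAIN = 200
N_TEST = 50


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def grammar(schema):
    return build_grammar(schema)


@pytest.fixture(scope="session")
def small_corpus(schema):
    """20 synthetic documents for fast structural tests."""
    return generate_corpus(FixtureConfig(n_documents=20, seed=7), schema)


@pytest.fixture(scope="session")
def train_corpus(schema):
    return generate_corpus(FixtureConfig(n_documents=N_TRAIN, seed=TRAIN_SEED), schema)


@pytest.fixture(scope="session")
def test_corpus(schema):
    return generate_corpus(FixtureConfig(n_documents=N_TEST, seed=TEST_SEED), schema)


@pytest.fixture(scope="session")
def trained_extractive(schema, train_corpus):
    return train_extractive(
        train_corpus, schema, TrainingConfig(epochs=20, seed=RUN_SEED)
    )


@pytest.fixture(scope="session")
def trained_generative(schema, train_corpus):
    return train_generative(
        train_corpus, schema, TrainingConfig(epochs=30, seed=RUN_SEED)
    )
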