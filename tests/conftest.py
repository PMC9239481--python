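import numpy as np
import pytest

from wcrf.encoder import EncoderConfig
from wcrf.model import CRFTagger, TrainingConfig
from wcrf.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def tiny_corpus():
    """Ten short sentences with a strong word-class signal (overfittable)."""
    cfg = GeneratorConfig(
        n_sentences=10,
        mean_length=10,
        max_length=15,
        vocab_size=80,
        emission_sharpness=0.9,
        seed=5,
    )
    corpus, truth = generate_corpus(cfg)
    return corpus, truth


@pytest.fixture(scope="session")
def small_encoder():
    def make(seed=0, **kw):
        kw.setdefault("embed_dim", 16)
        kw.setdefault("hidden_dim", 16)
        kw.setdefault("dropout_rate", 0.0)
        return EncoderConfig(vocab_size=1, seed=seed, **kw)

    return make


@pytest.fixture(scope="session")
def overfit_results(tiny_corpus, small_encoder):
    """wCRF model memorizing the tiny corpus (shared across tests)."""
    corpus, _ = tiny_corpus
    cfg = TrainingConfig(
        loss_kind="wcrf", epochs=200, learning_rate=0.01, seed=0, encoder=small_encoder()
    )
    return CRFTagger(corpus, cfg).fit()


def random_potentials(rng, n=None, k=None):
    from wcrf.crf import PotentialTables

    n = n if n is not None else int(rng.integers(1, 7))
    k = k if k is not None else int(rng.integers(1, 5))
    return PotentialTables(rng.normal(size=(n, k)), rng.normal(size=(k + 2, k + 2)))
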