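"""Shared session fixtures: synthetic corpus, toy-scale trained checkpoints.

Training happens once per session at desk scale (600-molecule corpus,
2-block / 4-head / 64-d transformers) so that every test exercising a
trained model shares the same checkpoints.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardioforge import features
from cardioforge.predictors import PredictorConfig, TrainRecipe, train_predictor
from cardioforge.synthetic import (
    PlantedActivitySpec,
    SyntheticCorpusSpec,
    make_corpus,
    make_labeled_set,
)
from cardioforge.tokenizer import build_vocabulary, preprocess_corpus
from cardioforge.transformer import (
    TransformerConfig,
    TransformerTrainSettings,
    train_bidirectional,
    train_generator,
)

TOY_MAX_CONTENT = 60
TOY_BLOCK = TOY_MAX_CONTENT + 2


@pytest.fixture(scope="session")
def toy_corpus() -> list[str]:
    return make_corpus(SyntheticCorpusSpec(n_molecules=600, seed=0))


@pytest.fixture(scope="session")
def toy_vocab(toy_corpus):
    return build_vocabulary(toy_corpus, min_count=1)


@pytest.fixture(scope="session")
def toy_sequences(toy_corpus, toy_vocab):
    return preprocess_corpus(toy_corpus, toy_vocab, max_content_len=TOY_MAX_CONTENT)


@pytest.fixture(scope="session")
def labeled_records(toy_corpus):
    return make_labeled_set(toy_corpus, PlantedActivitySpec(seed=0))


def _toy_config(vocab, conditioned: bool) -> TransformerConfig:
    return TransformerConfig(vocab_size=len(vocab), block_len=TOY_BLOCK, n_blocks=2,
                             n_heads=4, embed_dim=64, dropout=0.1, conditioned=conditioned)


@pytest.fixture(scope="session")
def featurizer_ckpt(toy_sequences, toy_vocab):
    ckpt, _ = train_bidirectional(
        toy_sequences, toy_vocab, _toy_config(toy_vocab, conditioned=False),
        TransformerTrainSettings(epochs=8, batch_size=64, lr=1e-3, seed=0))
    return ckpt


@pytest.fixture(scope="session")
def generator_ckpt(toy_corpus, toy_vocab):
    ckpt, history = train_generator(
        toy_corpus, toy_vocab, _toy_config(toy_vocab, conditioned=True),
        TransformerTrainSettings(epochs=60, batch_size=64, lr=1e-3, seed=0),
        max_content_len=TOY_MAX_CONTENT)
    ckpt.meta["fixture_loss_history"] = history
    return ckpt


TOY_PREDICTOR_KW = dict(transformer_dim=64, branch_hidden=64, gat_hidden=32,
                        gat_heads=4, fused_hidden=128)


@pytest.fixture(scope="session")
def herg_regressor(labeled_records, featurizer_ckpt):
    config = PredictorConfig(task="regression", channel="hERG", **TOY_PREDICTOR_KW)
    return train_predictor(labeled_records, featurizer_ckpt, config,
                           TrainRecipe(epochs=25, batch_size=32, lr=1e-3), seed=0)


@pytest.fixture(scope="session")
def corpus_properties(toy_corpus) -> np.ndarray:
    return np.stack([features.physchem_properties(s).as_array() for s in toy_corpus])
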