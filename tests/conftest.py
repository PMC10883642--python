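"""Shared fixtures.

The trained translator is expensive (minutes of CPU), so one desk-scale
model is trained once per session on the standard 200-molecule synthetic
corpus and shared by the translation-accuracy, round-trip and
end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from latentmol.fixtures import FixtureSpec, generate_corpus
from latentmol.translator import Seq2SeqTranslator, TranslatorConfig, train
from latentmol.chem_io import Vocabulary

CORPUS_SEED = 42
TRAIN_SEED = 11


@pytest.fixture(scope="session")
def corpus200():
    return generate_corpus(FixtureSpec(n_molecules=200, seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def trained_translator(corpus200):
    """Desk-scale translator trained to convergence on the fixture corpus
    (10 enumerations per molecule, 9:1 molecule-level split)."""
    cfg = TranslatorConfig.desk_scale(seed=7)
    model, report = train(
        corpus200, cfg, enumerations_per_molecule=10,
        split_fraction=0.1, rng_seed=TRAIN_SEED,
    )
    return model, report


@pytest.fixture(scope="session")
def heldout_records(corpus200):
    """The molecules held out by the session training split (recomputed
    with the same seed and split logic as latentmol.translator.train)."""
    valid = [r for r in corpus200 if r.valid]
    rng = np.random.default_rng(TRAIN_SEED)
    order = rng.permutation(len(valid))
    n_test = max(1, round(0.1 * len(valid)))
    return [valid[i] for i in order[:n_test]]


@pytest.fixture()
def untrained_tiny_model():
    """Small untrained model for architecture-contract tests."""
    vocab = Vocabulary.from_corpus(
        ["CCO", "c1ccccc1", "CC(N)=O", "ClCCBr", "C1CCOC1", "[nH]"]
    )
    cfg = TranslatorConfig.desk_scale(
        encoder_layer_units=(16, 16, 16), decoder_layer_units=(16, 16, 16),
        embedding_dim=8, seed=5, max_decode_len=30,
    )
    return Seq2SeqTranslator(vocab, cfg)
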