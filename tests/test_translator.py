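"""Translator architecture contracts, decoding and training behaviour.

Fast tests use small untrained models; the convergence-dependent checks
share the session-scoped trained model.
"""

import numpy as np
import pytest

from latentmol.chem_io import Vocabulary, canonicalize
from latentmol.errors import CorpusTooSmall, DimensionError
from latentmol.fixtures import FixtureSpec, generate_corpus
from latentmol.translator import (
    Seq2SeqTranslator,
    TranslatorConfig,
    char_accuracy,
    round_trip_rate,
    train,
)


class TestCharAccuracy:
    @pytest.mark.parametrize(
        "pred,truth,expected",
        [
            ("CCO", "CCO", 1.0),
            ("CCN", "CCO", 2 / 3),
            ("", "CCO", 0.0),
            ("CC", "CCO", 1.0),       # matches over predicted length
            ("CCOO", "CCO", 3 / 4),
        ],
    )
    def test_examples(self, pred, truth, expected):
        assert char_accuracy(pred, truth) == pytest.approx(expected)


class TestArchitectureContracts:
    def test_latent_dimension_and_range_any_model_state(self,
                                                        untrained_tiny_model):
        """The bottleneck forces 512 tanh-bounded components regardless of
        training state."""
        m = untrained_tiny_model
        Z = m.encode(["CCO", "c1ccccc1", "ClCCBr"])
        assert Z.shape == (3, 512)
        assert np.abs(Z).max() <= 1.0

    def test_encode_deterministic(self, untrained_tiny_model):
        m = untrained_tiny_model
        a = m.encode(["CC(N)=O"])
        b = m.encode(["CC(N)=O"])
        assert np.array_equal(a, b)

    def test_enumerations_encode_to_different_vectors(self,
                                                      untrained_tiny_model):
        m = untrained_tiny_model
        Z = m.encode(["OCC", "C(O)C"])
        assert not np.array_equal(Z[0], Z[1])

    def test_decode_wrong_dimension_raises(self, untrained_tiny_model):
        with pytest.raises(DimensionError):
            untrained_tiny_model.decode(np.zeros(511))
        with pytest.raises(DimensionError):
            untrained_tiny_model.greedy_decode_batch(np.zeros((2, 100)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TranslatorConfig(dropout=1.5)
        with pytest.raises(ValueError):
            TranslatorConfig(embedding_noise_sd=-1)

    def test_profiles(self):
        full = TranslatorConfig()
        assert full.full_profile
        desk = TranslatorConfig.desk_scale()
        assert desk.bottleneck_dim == 512
        assert not desk.full_profile


class TestDecoding:
    def test_beam_one_equals_greedy(self, untrained_tiny_model):
        """Beam search with width 1 is exactly greedy decoding, token for
        token, for arbitrary latent points and any model state."""
        m = untrained_tiny_model
        rng = np.random.default_rng(4)
        for _ in range(5):
            z = rng.uniform(-1, 1, 512)
            beam = m.decode(z, beam_width=1)[0][0]
            greedy = m.greedy_decode_batch(z[None, :])[0]
            assert beam == greedy

    def test_random_latents_never_raise(self, untrained_tiny_model):
        m = untrained_tiny_model
        rng = np.random.default_rng(8)
        for _ in range(3):
            results = m.decode(rng.uniform(-1, 1, 512), beam_width=4)
            assert 1 <= len(results) <= 4
            for smi, logp, valid in results:
                assert isinstance(valid, bool)
                assert logp <= 0.0

    def test_beam_results_sorted_by_score(self, untrained_tiny_model):
        results = untrained_tiny_model.decode(np.zeros(512), beam_width=5)
        scores = [r[1] for r in results]
        assert scores == sorted(scores, reverse=True)


class TestTrainingLoop:
    def test_corpus_too_small(self):
        corpus = generate_corpus(FixtureSpec(1, seed=0))
        with pytest.raises(CorpusTooSmall):
            train(corpus, TranslatorConfig.desk_scale(max_epochs=1))

    def test_short_training_smoke_and_report(self):
        """Two epochs on a small corpus: loss falls, report is populated,
        and the run is reproducible."""
        corpus = generate_corpus(FixtureSpec(30, seed=3))
        cfg = TranslatorConfig.desk_scale(
            encoder_layer_units=(24, 24, 24), decoder_layer_units=(24, 24, 24),
            embedding_dim=16, seed=2, max_epochs=2, patience=5,
        )
        model, report = train(corpus, cfg, enumerations_per_molecule=3,
                              split_fraction=0.1, rng_seed=5)
        assert len(report.loss) == 2
        assert report.loss[1] < report.loss[0]
        assert all(0 <= a <= 1 for a in report.heldout_char_accuracy)
        assert report.n_train_pairs > report.n_heldout_pairs

        model2, report2 = train(corpus, cfg, enumerations_per_molecule=3,
                                split_fraction=0.1, rng_seed=5)
        assert report2.loss == report.loss
        for k in model.params:
            assert np.array_equal(model.params[k], model2.params[k])

    def test_degenerate_autoencoder_trains(self):
        corpus = generate_corpus(FixtureSpec(20, seed=9))
        cfg = TranslatorConfig.desk_scale(
            encoder_layer_units=(16, 16, 16), decoder_layer_units=(16, 16, 16),
            embedding_dim=8, seed=0, max_epochs=2, patience=5,
        )
        model, report = train(corpus, cfg, enumerations_per_molecule=1,
                              split_fraction=0.1, rng_seed=1)
        assert report.loss[-1] < report.loss[0] * 1.5

    def test_loop_accuracy_matches_oracle(self):
        """The teacher-forced accuracy reported by the training loop equals
        the character-accuracy oracle applied to argmax predictions."""
        corpus = generate_corpus(FixtureSpec(20, seed=9))
        cfg = TranslatorConfig.desk_scale(
            encoder_layer_units=(16, 16, 16), decoder_layer_units=(16, 16, 16),
            embedding_dim=8, seed=0, max_epochs=1, patience=5,
        )
        model, _ = train(corpus, cfg, enumerations_per_molecule=2,
                         split_fraction=0.2, rng_seed=1)
        vocab = model.vocab
        smiles = [r.canonical_smiles for r in corpus[:8]]
        enc = [vocab.encode(s) for s in smiles]
        dec = [vocab.encode(s) for s in smiles]
        _, loop_acc, n_tokens = model.teacher_forced_metrics(enc, dec)
        preds = model.teacher_forced_predictions(enc, dec)
        matches = total = 0
        for pred, s in zip(preds, smiles):
            target = list(vocab.encode(s)[1:])  # interior + end marker
            matches += sum(p == t for p, t in zip(pred, target))
            total += len(target)
        assert total == n_tokens
        assert loop_acc == pytest.approx(matches / total, abs=1e-6)

    def test_untrained_round_trip_rate_near_zero(self, untrained_tiny_model):
        # untrained weights essentially never reproduce the input
        from latentmol.chem_io import MoleculeRecord

        records = [MoleculeRecord.from_smiles(s)
                   for s in ["CCO", "c1ccccc1", "ClCCBr", "CC(N)=O"]]
        rate = round_trip_rate(untrained_tiny_model, records)
        assert rate <= 0.25


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path, untrained_tiny_model):
        m = untrained_tiny_model
        m.save(tmp_path / "ckpt")
        loaded = Seq2SeqTranslator.load(tmp_path / "ckpt")
        Z_a = m.encode(["CCO", "ClCCBr"])
        Z_b = loaded.encode(["CCO", "ClCCBr"])
        assert np.array_equal(Z_a, Z_b)
        z = np.zeros(512)
        assert m.decode(z, 3) == loaded.decode(z, 3)


class TestTrainedModel:
    """Convergence-dependent checks on the session-trained translator."""

    def test_heldout_round_trip(self, trained_translator, heldout_records):
        """A converged desk-scale model reproduces the large majority of
        held-out molecules from their own encodings (0.75-0.85 across
        training seeds at this corpus size)."""
        model, _ = trained_translator
        rate = round_trip_rate(model, heldout_records, beam_width=1)
        assert rate >= 0.6

    def test_training_round_trip_near_perfect(self, trained_translator,
                                              corpus200, heldout_records):
        heldout = {r.canonical_smiles for r in heldout_records}
        train_recs = [r for r in corpus200
                      if r.canonical_smiles not in heldout][:30]
        model, _ = trained_translator
        assert round_trip_rate(model, train_recs, beam_width=1) >= 0.9

    def test_enumerations_decode_to_same_molecule(self, trained_translator,
                                                  heldout_records):
        from latentmol.chem_io import enumerate_smiles

        model, _ = trained_translator
        hits = total = 0
        for rec in heldout_records[:10]:
            enums = enumerate_smiles(rec.canonical_smiles, 3, seed=5)
            Z = model.encode(enums)
            for smi in model.greedy_decode_batch(Z):
                total += 1
                try:
                    hits += canonicalize(smi) == rec.canonical_smiles
                except Exception:
                    pass
        assert hits / total >= 0.5

    def test_accuracy_trend_non_decreasing(self, trained_translator):
        """Held-out accuracy rises then stabilizes: smoothed trajectory is
        non-decreasing within tolerance."""
        _, report = trained_translator
        acc = np.asarray(report.heldout_char_accuracy)
        w = max(3, len(acc) // 10)
        smooth = np.convolve(acc, np.ones(w) / w, mode="valid")
        drops = np.diff(smooth)
        assert drops.min() > -0.03
        assert smooth[-1] > smooth[0]
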