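"""Reversible SMILES translator: recurrent encoder, tanh bottleneck, decoder.

The model maps an enumerated SMILES rendering of a molecule to a single
512-dimensional latent vector and back to the canonical SMILES.  The
encoder is three stacked GRU layers followed by a fully connected
bottleneck with hyperbolic-tangent activation, so every latent component
lies in [-1, 1] by construction.  The decoder is three stacked GRU layers
whose initial hidden states are learned linear maps of the latent vector;
the latent vector is additionally concatenated to the input embedding at
every decoding step.  Training pairs an enumerated rendering (encoder
input) with the canonical SMILES (decoder target) under teacher forcing
and per-token cross-entropy, which forces molecule-level rather than
string-level features into the latent space.

Inference decoding uses beam search over cumulative log-probability;
width 1 reduces exactly to greedy decoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import F32
from .chem_io import (
    LATENT_DIM,
    MoleculeRecord,
    Vocabulary,
    canonicalize,
    enumerate_smiles,
)
from .errors import (
    CorpusTooSmall,
    DimensionError,
    InvalidSmiles,
    NonFiniteLoss,
)


@dataclass
class TranslatorConfig:
    """Architecture and training hyperparameters.

    The full profile (the defaults) uses decoder GRU layers of 1024, 512
    and 256 units with the encoder mirroring them in reverse; the
    bottleneck is 512 units with tanh activation.  ``desk_scale`` returns
    a reduced profile (hidden sizes 64, bottleneck still 512) that trains
    in minutes on one CPU and is the profile used by the test suite.
    """

    encoder_layer_units: tuple[int, int, int] = (256, 512, 1024)
    decoder_layer_units: tuple[int, int, int] = (1024, 512, 256)
    bottleneck_dim: int = LATENT_DIM
    embedding_dim: int = 128
    dropout: float = 0.15
    embedding_noise_sd: float = 0.05
    batch_size: int = 64
    beam_width: int = 5
    max_decode_len: int = 120
    seed: int = 0
    # training schedule
    learning_rate: float = 1e-3
    lr_decay: float = 0.05
    weight_decay: float = 0.0
    max_epochs: int = 200
    patience: int = 8
    min_delta: float = 1e-3
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.embedding_noise_sd < 0:
            raise ValueError("embedding_noise_sd must be >= 0")

    @property
    def full_profile(self) -> bool:
        """True for the full-size architecture (1024/512/256 decoder with
        the 512-d bottleneck); reduced test profiles return False."""
        return (
            self.bottleneck_dim == LATENT_DIM
            and tuple(self.decoder_layer_units) == (1024, 512, 256)
        )

    @classmethod
    def desk_scale(cls, **overrides) -> "TranslatorConfig":
        """Reduced profile for CI-scale corpora (96-unit GRU layers)."""
        base = dict(
            encoder_layer_units=(96, 96, 96),
            decoder_layer_units=(96, 96, 96),
            embedding_dim=64,
            max_decode_len=80,
            learning_rate=2e-3,
            lr_decay=0.01,
            weight_decay=0.01,
            max_epochs=220,
            patience=80,
            min_delta=1e-4,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainingReport:
    """Loss and character-accuracy trajectory for one training run."""

    steps: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    train_char_accuracy: list[float] = field(default_factory=list)
    heldout_char_accuracy: list[float] = field(default_factory=list)
    total_steps: int = 0
    seed: int = 0
    converged: bool = False
    best_heldout_char_accuracy: float = 0.0
    n_train_pairs: int = 0
    n_heldout_pairs: int = 0

    def record(self, step: int, loss: float, train_acc: float, test_acc: float) -> None:
        self.steps.append(step)
        self.loss.append(loss)
        self.train_char_accuracy.append(train_acc)
        self.heldout_char_accuracy.append(test_acc)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def char_accuracy(predicted: str, truth: str) -> float:
    """Fraction of positions where the prediction matches the truth,
    divided by the predicted length; empty prediction scores 0."""
    if not predicted:
        return 0.0
    matches = sum(1 for p, t in zip(predicted, truth) if p == t)
    return matches / len(predicted)


class Seq2SeqTranslator:
    """Encoder/decoder pair over a fixed vocabulary.

    Parameters are float32 NumPy arrays in a flat dict; all stochastic
    behaviour (init, dropout, noise) flows from ``config.seed``.
    """

    def __init__(self, vocab: Vocabulary, config: TranslatorConfig):
        self.vocab = vocab
        self.config = config
        self.max_decode_len = config.max_decode_len
        rng = np.random.default_rng(config.seed)
        V = len(vocab)
        E = config.embedding_dim
        Z = config.bottleneck_dim
        enc_units = list(config.encoder_layer_units)
        dec_units = list(config.decoder_layer_units)
        p: dict[str, np.ndarray] = {}
        p["emb_enc"] = (0.1 * rng.standard_normal((V, E))).astype(F32)
        p["emb_dec"] = (0.1 * rng.standard_normal((V, E))).astype(F32)
        in_dim = E
        for l, H in enumerate(enc_units):
            for k, v in _nn.init_gru(rng, in_dim, H).items():
                p[f"enc{l}.{k}"] = v
            in_dim = H
        for k, v in _nn.init_dense(rng, enc_units[-1], Z).items():
            p[f"bottle.{k}"] = v
        in_dim = E + Z
        for l, H in enumerate(dec_units):
            for k, v in _nn.init_dense(rng, Z, H).items():
                p[f"init{l}.{k}"] = v
            for k, v in _nn.init_gru(rng, in_dim, H).items():
                p[f"dec{l}.{k}"] = v
            in_dim = H
        for k, v in _nn.init_dense(rng, dec_units[-1], V).items():
            p[f"out.{k}"] = v
        self.params = p
        self._train_rng = np.random.default_rng(config.seed + 1)

    # -- parameter plumbing -------------------------------------------------

    def _sub(self, prefix: str) -> dict:
        n = len(prefix) + 1
        return {k[n:]: v for k, v in self.params.items() if k.startswith(prefix + ".")}

    def zero_grads(self) -> dict:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    # -- batch construction -------------------------------------------------

    def _pad_batch(self, seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Stack id sequences into (T, B) index and (T, B) mask arrays."""
        B = len(seqs)
        T = max(len(s) for s in seqs)
        ids = np.full((T, B), self.vocab.pad, dtype=np.int64)
        mask = np.zeros((T, B), dtype=F32)
        for j, s in enumerate(seqs):
            ids[: len(s), j] = s
            mask[: len(s), j] = 1.0
        return ids, mask

    # -- forward / backward -------------------------------------------------

    def _embed(self, table: np.ndarray, ids: np.ndarray, train: bool):
        x = table[ids]  # (T, B, E)
        drop_mask = None
        if train:
            cfg = self.config
            if cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                drop_mask = (
                    self._train_rng.random(x.shape) < keep
                ).astype(F32) / F32(keep)
                x = x * drop_mask
            if cfg.embedding_noise_sd > 0:
                x = x + self._train_rng.normal(
                    0.0, cfg.embedding_noise_sd, size=x.shape
                ).astype(F32)
        return x.astype(F32, copy=False), drop_mask

    def _forward(self, enc_ids, enc_mask, dec_in, dec_tgt, dec_mask, train: bool):
        cfg = self.config
        B = enc_ids.shape[1]
        enc_x, enc_drop = self._embed(self.params["emb_enc"], enc_ids, train)
        enc_caches = []
        x = enc_x
        h_last = None
        for l, H in enumerate(cfg.encoder_layer_units):
            h0 = np.zeros((B, H), dtype=F32)
            hs, h_last, cache = _nn.gru_forward(self._sub(f"enc{l}"), x, h0, enc_mask)
            enc_caches.append(cache)
            x = hs
        z_pre = h_last @ self.params["bottle.W"] + self.params["bottle.b"]
        z = np.tanh(z_pre)

        dec_h0 = []
        for l in range(len(cfg.decoder_layer_units)):
            h0 = np.tanh(z @ self.params[f"init{l}.W"] + self.params[f"init{l}.b"])
            dec_h0.append(h0)

        dec_x_emb, dec_drop = self._embed(self.params["emb_dec"], dec_in, train)
        T_d = dec_in.shape[0]
        z_tile = np.broadcast_to(z, (T_d, B, z.shape[1]))
        x = np.concatenate([dec_x_emb, z_tile], axis=2)
        dec_caches = []
        for l in range(len(cfg.decoder_layer_units)):
            hs, _, cache = _nn.gru_forward(self._sub(f"dec{l}"), x, dec_h0[l], dec_mask)
            dec_caches.append(cache)
            x = hs
        H_top = x.shape[2]
        flat = x.reshape(T_d * B, H_top)
        logits = flat @ self.params["out.W"] + self.params["out.b"]
        loss, acc, d_logits = _nn.softmax_xent(
            logits, dec_tgt.reshape(-1), dec_mask.reshape(-1)
        )
        cache = dict(
            enc_ids=enc_ids, enc_caches=enc_caches, enc_drop=enc_drop,
            h_last=h_last, z=z, dec_h0=dec_h0, dec_ids=dec_in,
            dec_caches=dec_caches, dec_drop=dec_drop, flat=flat,
            d_logits=d_logits, B=B, T_d=T_d,
        )
        return loss, acc, cache

    def _backward(self, cache: dict) -> dict:
        cfg = self.config
        grads = self.zero_grads()
        B, T_d = cache["B"], cache["T_d"]
        E = cfg.embedding_dim
        Z = cfg.bottleneck_dim
        z = cache["z"]

        grads["out.W"] += cache["flat"].T @ cache["d_logits"]
        grads["out.b"] += cache["d_logits"].sum(axis=0)
        H_top = self.params["out.W"].shape[0]
        d_hs = (cache["d_logits"] @ self.params["out.W"].T).reshape(T_d, B, H_top)

        dz = np.zeros((B, Z), dtype=F32)
        n_dec = len(cfg.decoder_layer_units)
        d_x = None
        for l in range(n_dec - 1, -1, -1):
            g = {k: grads[f"dec{l}.{k}"] for k in ("Wg", "bg", "Wc", "bc")}
            d_seq = d_hs if l == n_dec - 1 else d_x
            H = cfg.decoder_layer_units[l]
            d_x, d_h0 = _nn.gru_backward(
                self._sub(f"dec{l}"), cache["dec_caches"][l],
                d_seq, np.zeros((B, H), dtype=F32), g,
            )
            h0 = cache["dec_h0"][l]
            d_pre = d_h0 * (1.0 - h0 * h0)
            grads[f"init{l}.W"] += z.T @ d_pre
            grads[f"init{l}.b"] += d_pre.sum(axis=0)
            dz += d_pre @ self.params[f"init{l}.W"].T
        d_emb = d_x[:, :, :E]
        dz += d_x[:, :, E:].sum(axis=0)
        if cache["dec_drop"] is not None:
            d_emb = d_emb * cache["dec_drop"]
        np.add.at(grads["emb_dec"], cache["dec_ids"], d_emb)

        d_zpre = dz * (1.0 - z * z)
        grads["bottle.W"] += cache["h_last"].T @ d_zpre
        grads["bottle.b"] += d_zpre.sum(axis=0)
        d_h_last = d_zpre @ self.params["bottle.W"].T

        n_enc = len(cfg.encoder_layer_units)
        d_seq = None
        for l in range(n_enc - 1, -1, -1):
            g = {k: grads[f"enc{l}.{k}"] for k in ("Wg", "bg", "Wc", "bc")}
            dlast = d_h_last if l == n_enc - 1 else np.zeros(
                (B, cfg.encoder_layer_units[l]), dtype=F32
            )
            d_seq, _ = _nn.gru_backward(
                self._sub(f"enc{l}"), cache["enc_caches"][l], d_seq, dlast, g,
            )
        if cache["enc_drop"] is not None:
            d_seq = d_seq * cache["enc_drop"]
        np.add.at(grads["emb_enc"], cache["enc_ids"], d_seq)
        return grads

    def train_step(self, enc_seqs, dec_seqs) -> tuple[float, float, dict]:
        """One teacher-forced step: returns (loss, char accuracy, grads)."""
        enc_ids, enc_mask = self._pad_batch(enc_seqs)
        full_ids, full_mask = self._pad_batch(dec_seqs)
        dec_in, dec_tgt = full_ids[:-1], full_ids[1:]
        dec_mask = full_mask[1:]
        loss, acc, cache = self._forward(
            enc_ids, enc_mask, dec_in, dec_tgt, dec_mask, train=True
        )
        if not np.isfinite(loss):
            raise NonFiniteLoss(f"loss diverged: {loss}")
        return loss, acc, self._backward(cache)

    def teacher_forced_metrics(self, enc_seqs, dec_seqs) -> tuple[float, float, int]:
        """(loss, micro char accuracy, n tokens) without dropout/noise."""
        enc_ids, enc_mask = self._pad_batch(enc_seqs)
        full_ids, full_mask = self._pad_batch(dec_seqs)
        loss, acc, _ = self._forward(
            enc_ids, enc_mask, full_ids[:-1], full_ids[1:], full_mask[1:],
            train=False,
        )
        return loss, acc, int(full_mask[1:].sum())

    def teacher_forced_predictions(self, enc_seqs, dec_seqs) -> list[list[int]]:
        """Argmax token predictions under teacher forcing, one list per
        sequence, truncated to the true target length (for checking the
        training-loop accuracy against the character-accuracy oracle)."""
        enc_ids, enc_mask = self._pad_batch(enc_seqs)
        full_ids, full_mask = self._pad_batch(dec_seqs)
        dec_in, dec_tgt = full_ids[:-1], full_ids[1:]
        dec_mask = full_mask[1:]
        _, _, cache = self._forward(
            enc_ids, enc_mask, dec_in, dec_tgt, dec_mask, train=False
        )
        T_d, B = dec_tgt.shape
        logits = cache["flat"] @ self.params["out.W"] + self.params["out.b"]
        pred = logits.argmax(axis=1).reshape(T_d, B)
        out = []
        for j in range(B):
            n = int(dec_mask[:, j].sum())
            out.append([int(t) for t in pred[:n, j]])
        return out

    # -- inference ----------------------------------------------------------

    def encode(self, smiles_batch: list[str], batch_size: int = 256) -> np.ndarray:
        """Latent vectors for a list of SMILES, shape (n, bottleneck_dim).

        Deterministic for fixed weights; every component is in [-1, 1]
        because of the tanh bottleneck.
        """
        seqs = [self.vocab.encode(s) for s in smiles_batch]
        out = np.empty((len(seqs), self.config.bottleneck_dim), dtype=np.float64)
        for lo in range(0, len(seqs), batch_size):
            chunk = seqs[lo : lo + batch_size]
            enc_ids, enc_mask = self._pad_batch(chunk)
            x, _ = self._embed(self.params["emb_enc"], enc_ids, train=False)
            h_last = None
            for l, H in enumerate(self.config.encoder_layer_units):
                h0 = np.zeros((len(chunk), H), dtype=F32)
                x, h_last, _ = _nn.gru_forward(self._sub(f"enc{l}"), x, h0, enc_mask)
            z = np.tanh(h_last @ self.params["bottle.W"] + self.params["bottle.b"])
            out[lo : lo + len(chunk)] = z
        return out

    def _check_latent(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=F32).reshape(-1)
        if z.shape[0] != self.config.bottleneck_dim:
            raise DimensionError(
                f"latent vector has {z.shape[0]} components, "
                f"expected {self.config.bottleneck_dim}"
            )
        return z

    def _decoder_step(self, tokens: np.ndarray, hs: list[np.ndarray],
                      z_rows: np.ndarray):
        """One decoder step for a batch of beams/particles.

        tokens: (B,) previous token ids; hs: per-layer hidden states
        (B, H); z_rows: (B, Z).  Returns (log-probs (B, V), new hidden).
        """
        x = np.concatenate([self.params["emb_dec"][tokens], z_rows], axis=1)
        new_hs = []
        for l in range(len(self.config.decoder_layer_units)):
            h = _nn.gru_cell(self._sub(f"dec{l}"), x, hs[l])
            new_hs.append(h)
            x = h
        logits = x @ self.params["out.W"] + self.params["out.b"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        logprobs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        return logprobs, new_hs

    def _init_decoder_state(self, z_rows: np.ndarray) -> list[np.ndarray]:
        return [
            np.tanh(z_rows @ self.params[f"init{l}.W"] + self.params[f"init{l}.b"])
            for l in range(len(self.config.decoder_layer_units))
        ]

    def decode(self, z, beam_width: int | None = None) -> list[tuple[str, float, bool]]:
        """Beam-search decode one latent vector.

        Returns up to ``beam_width`` complete sequences as
        (smiles, cumulative log-probability, valid) tuples, ordered by
        descending log-probability; ties break on lexicographic token
        order, so width 1 is exactly greedy argmax decoding.  Arbitrary
        latent vectors may decode to syntactically invalid strings; those
        are returned with ``valid=False``, never raised.
        """
        from rdkit import Chem

        z = self._check_latent(z)
        if beam_width is None:
            beam_width = self.config.beam_width
        if beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        end = self.vocab.end
        # beams: (neg tie-break key is implicit in ordering) list of
        # [logp, token list, hidden states, done]
        beams = [[0.0, [self.vocab.start], None, False]]
        z_row = z[None, :]
        beams[0][2] = self._init_decoder_state(z_row)
        for _ in range(self.max_decode_len):
            active = [b for b in beams if not b[3]]
            if not active:
                break
            toks = np.array([b[1][-1] for b in active], dtype=np.int64)
            hs = [
                np.concatenate([b[2][l] for b in active], axis=0)
                for l in range(len(self.config.decoder_layer_units))
            ]
            zr = np.repeat(z_row, len(active), axis=0)
            logprobs, new_hs = self._decoder_step(toks, hs, zr)
            candidates = [b for b in beams if b[3]]
            for j, b in enumerate(active):
                lp = logprobs[j]
                top = np.argsort(-lp, kind="stable")[:beam_width]
                hs_j = [h[j : j + 1] for h in new_hs]
                for tok in top:
                    tok = int(tok)
                    candidates.append(
                        [b[0] + float(lp[tok]), b[1] + [tok], hs_j, tok == end]
                    )
            candidates.sort(key=lambda b: (-b[0], tuple(b[1])))
            beams = candidates[:beam_width]
        results = []
        for logp, toks, _, done in beams:
            smi = self.vocab.decode(toks)
            valid = Chem.MolFromSmiles(smi) is not None if smi else False
            results.append((smi, logp, valid))
        results.sort(key=lambda r: (-r[1], r[0]))
        return results

    def greedy_decode_batch(self, Z: np.ndarray) -> list[str]:
        """Greedy decode a batch of latent vectors (rows of Z) at once."""
        Z = np.asarray(Z, dtype=F32)
        if Z.ndim == 1:
            Z = Z[None, :]
        if Z.shape[1] != self.config.bottleneck_dim:
            raise DimensionError(
                f"latent vectors have {Z.shape[1]} components, "
                f"expected {self.config.bottleneck_dim}"
            )
        B = Z.shape[0]
        hs = self._init_decoder_state(Z)
        tokens = np.full(B, self.vocab.start, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        outputs: list[list[int]] = [[] for _ in range(B)]
        for _ in range(self.max_decode_len):
            logprobs, hs = self._decoder_step(tokens, hs, Z)
            tokens = logprobs.argmax(axis=1)
            for j in range(B):
                if not done[j]:
                    if tokens[j] == self.vocab.end:
                        done[j] = True
                    else:
                        outputs[j].append(int(tokens[j]))
            if done.all():
                break
        return [self.vocab.decode(toks) for toks in outputs]

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["encoder_layer_units"] = list(cfg["encoder_layer_units"])
        cfg["decoder_layer_units"] = list(cfg["decoder_layer_units"])
        cfg["max_decode_len_effective"] = self.max_decode_len
        (d / "config.json").write_text(json.dumps(cfg, indent=2))
        (d / "vocab.json").write_text(json.dumps(self.vocab.to_dict(), indent=2))
        np.savez(d / "weights.npz", **self.params)

    @classmethod
    def load(cls, directory: str | Path) -> "Seq2SeqTranslator":
        d = Path(directory)
        cfg = json.loads((d / "config.json").read_text())
        effective = cfg.pop("max_decode_len_effective", None)
        cfg["encoder_layer_units"] = tuple(cfg["encoder_layer_units"])
        cfg["decoder_layer_units"] = tuple(cfg["decoder_layer_units"])
        config = TranslatorConfig(**cfg)
        vocab = Vocabulary.from_dict(json.loads((d / "vocab.json").read_text()))
        model = cls(vocab, config)
        with np.load(d / "weights.npz") as data:
            for k in model.params:
                model.params[k] = data[k]
        if effective is not None:
            model.max_decode_len = int(effective)
        return model


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _make_pairs(records, k, rng):
    """(enumerated rendering, canonical target) pairs grouped by molecule."""
    pairs_per_mol = []
    for rec in records:
        seed = int(rng.integers(2**31))
        enums = enumerate_smiles(rec.canonical_smiles, k, seed=seed)
        pairs_per_mol.append([(e, rec.canonical_smiles) for e in enums])
    return pairs_per_mol


def train(
    corpus: list[MoleculeRecord],
    config: TranslatorConfig,
    enumerations_per_molecule: int = 10,
    split_fraction: float = 0.1,
    rng_seed: int = 0,
) -> tuple[Seq2SeqTranslator, TrainingReport]:
    """Train a translator on (enumerated -> canonical) SMILES pairs.

    The corpus is split by molecule (all renderings of a molecule land in
    one split) with ``split_fraction`` held out.  Training stops when the
    held-out teacher-forced character accuracy has not improved by
    ``config.min_delta`` for ``config.patience`` consecutive epochs, and
    the best-scoring weights are restored.
    """
    valid = [r for r in corpus if r.valid]
    if len(valid) < 2:
        raise CorpusTooSmall(f"need at least 2 valid molecules, got {len(valid)}")
    if enumerations_per_molecule < 1:
        raise ValueError("enumerations_per_molecule must be >= 1")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(valid))
    n_test = max(1, round(split_fraction * len(valid)))
    test_records = [valid[i] for i in order[:n_test]]
    train_records = [valid[i] for i in order[n_test:]]
    if not train_records:
        raise CorpusTooSmall("split left no training molecules")

    train_groups = _make_pairs(train_records, enumerations_per_molecule, rng)
    test_groups = _make_pairs(test_records, enumerations_per_molecule, rng)
    train_pairs = [p for g in train_groups for p in g]
    test_pairs = [p for g in test_groups for p in g]

    all_strings = [s for pair in train_pairs + test_pairs for s in pair]
    vocab = Vocabulary.from_corpus(all_strings)
    model = Seq2SeqTranslator(vocab, config)
    longest = max(len(vocab.encode(s)) for s in all_strings)
    model.max_decode_len = min(config.max_decode_len, 2 * longest)

    enc_train = [vocab.encode(e) for e, _ in train_pairs]
    dec_train = [vocab.encode(c) for _, c in train_pairs]
    enc_test = [vocab.encode(e) for e, _ in test_pairs]
    dec_test = [vocab.encode(c) for _, c in test_pairs]

    report = TrainingReport(seed=rng_seed,
                            n_train_pairs=len(train_pairs),
                            n_heldout_pairs=len(test_pairs))
    opt = _nn.Adam(model.params, lr=config.learning_rate)
    B = config.batch_size
    n = len(enc_train)
    best_acc = -1.0
    best_params = None
    stale = 0
    step = 0

    def heldout_accuracy() -> float:
        correct = total = 0.0
        for lo in range(0, len(enc_test), 256):
            _, acc, ntok = model.teacher_forced_metrics(
                enc_test[lo : lo + 256], dec_test[lo : lo + 256]
            )
            correct += acc * ntok
            total += ntok
        return correct / max(total, 1.0)

    for epoch in range(config.max_epochs):
        # length-sorted batches (less padding), batch order shuffled
        perm = rng.permutation(n)
        perm = perm[np.argsort([len(enc_train[i]) for i in perm], kind="stable")]
        starts = list(range(0, n, B))
        rng.shuffle(starts)
        lr = config.learning_rate / (1.0 + config.lr_decay * epoch)
        ep_loss = ep_acc = ep_batches = 0.0
        for lo in starts:
            idx = perm[lo : lo + B]
            loss, acc, grads = model.train_step(
                [enc_train[i] for i in idx], [dec_train[i] for i in idx]
            )
            _nn.clip_grads(grads, config.grad_clip)
            opt.step(model.params, grads, lr=lr,
                     weight_decay=config.weight_decay)
            ep_loss += loss
            ep_acc += acc
            ep_batches += 1
            step += 1
        test_acc = heldout_accuracy()
        report.record(step, ep_loss / ep_batches, ep_acc / ep_batches, test_acc)
        if test_acc > best_acc + config.min_delta:
            best_acc = test_acc
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            if test_acc > best_acc:
                best_acc = test_acc
                best_params = {k: v.copy() for k, v in model.params.items()}
            stale += 1
            if stale >= config.patience:
                report.converged = True
                break
    if best_params is not None:
        model.params = best_params
    report.total_steps = step
    report.best_heldout_char_accuracy = best_acc
    return model, report


def round_trip_rate(
    model: Seq2SeqTranslator,
    molecules: list[MoleculeRecord],
    beam_width: int = 1,
) -> float:
    """Fraction of molecules whose top-ranked decode of their own encoding
    canonicalizes back to the input's canonical SMILES."""
    valid = [m for m in molecules if m.valid]
    if not valid:
        return 0.0
    Z = model.encode([m.canonical_smiles for m in valid])
    hits = 0
    if beam_width == 1:
        decoded = model.greedy_decode_batch(Z)
        for m, smi in zip(valid, decoded):
            try:
                hits += canonicalize(smi) == m.canonical_smiles
            except InvalidSmiles:
                pass
    else:
        for m, z in zip(valid, Z):
            results = model.decode(z, beam_width=beam_width)
            if results:
                smi = results[0][0]
                try:
                    hits += canonicalize(smi) == m.canonical_smiles
                except InvalidSmiles:
                    pass
    return hits / len(valid)
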