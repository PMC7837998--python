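"""BiLSTM-CRF sequence labeler with pluggable character embeddings.

A bidirectional LSTM (100 hidden units per direction) encodes each
character of a report; a linear projection maps the concatenated hidden
states to per-tag emission scores, which are decoded through the same
exact CRF inference core as the feature-based labeler (:mod:`hepanlp.crf`).
Training minimizes the negative CRF conditional log-likelihood with Adam.

The encoder and its backpropagation are implemented directly in NumPy,
which keeps training reproducible bit-for-bit given a seed and a fixed
BLAS, at the corpus sizes this package targets.

Character vectors come from one of three providers:

* a trainable lookup table (dimension 100), learned jointly;
* pretrained static vectors loaded from the standard whitespace-separated
  word-vector text format (:func:`load_pretrained_vectors`);
* a deterministic hash-based contextual encoder
  (:class:`HashContextualStub`) whose vectors depend on a character and
  its neighbor window, so identical characters in different contexts get
  different vectors.  It exercises the frozen contextual-provider path
  offline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .crf import crf_nll_and_grads, viterbi_decode
from .tagging import N_TAGS, TAGS, TAG_TO_INDEX, repair_orphan_i, validate_tags

UNK_TOKEN = "<unk>"


class EmbeddingProvider(Protocol):
    """Frozen per-character vector source.

    ``encode`` must return one vector per input character (after the
    model's truncation policy has been applied); ``dim`` is constant.
    """

    dim: int

    def encode(self, text: str) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Static word-vector text format


class StaticVectors:
    """Pretrained static character vectors; unknown characters map to the
    zero vector (the model adds a learned unknown offset on top)."""

    def __init__(self, table: dict[str, np.ndarray], dim: int):
        self.table = table
        self.dim = dim

    def __contains__(self, ch: str) -> bool:
        return ch in self.table

    def encode(self, text: str) -> np.ndarray:
        out = np.zeros((len(text), self.dim), dtype=np.float32)
        for i, ch in enumerate(text):
            vec = self.table.get(ch)
            if vec is not None:
                out[i] = vec
        return out

    def unknown_mask(self, text: str) -> np.ndarray:
        return np.array([ch not in self.table for ch in text], dtype=bool)


def load_pretrained_vectors(path: str | Path) -> StaticVectors:
    """Read the whitespace word-vector text format.

    First line may be a ``count dim`` header; every other line is
    ``token v1 … vd``.  Inconsistent dimensions raise with the line number.
    """
    table: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.rstrip("\n").split(" ")
            if not parts or parts == [""]:
                continue
            if lineno == 1 and len(parts) == 2:
                dim = int(parts[1])  # header: vocabulary count, dimension
                continue
            token, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
            if len(values) != dim:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} vector components, "
                    f"got {len(values)}"
                )
            table[token] = np.asarray(values, dtype=np.float32)
    return StaticVectors(table, dim or 0)


def write_vectors(path: str | Path, table: dict[str, np.ndarray], header: bool = True) -> None:
    """Inverse of :func:`load_pretrained_vectors` (used for round-trips)."""
    dim = len(next(iter(table.values()))) if table else 0
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(table)} {dim}\n")
        for token, vec in table.items():
            comps = " ".join(repr(float(v)) for v in vec)
            fh.write(f"{token} {comps}\n")


# ---------------------------------------------------------------------------
# Deterministic contextual stub


class HashContextualStub:
    """Hash-based stand-in for a contextual encoder.

    Each position's vector is a deterministic function of the character
    AND its ±``window`` neighbors, drawn unit-normal from a hash-seeded
    generator.  Same context → identical vector (cosine 1); different
    neighbors → different vector.
    """

    def __init__(self, dim: int = 100, window: int = 2, max_len: int = 256):
        self.dim = dim
        self.window = window
        self.max_len = max_len

    def encode(self, text: str) -> np.ndarray:
        if len(text) > self.max_len:
            raise ValueError(f"sequence length {len(text)} exceeds {self.max_len}")
        out = np.empty((len(text), self.dim), dtype=np.float32)
        for i in range(len(text)):
            lo = max(0, i - self.window)
            ctx = f"{text[lo:i]}|{text[i]}|{text[i + 1:i + 1 + self.window]}"
            digest = hashlib.blake2b(ctx.encode("utf-8"), digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            out[i] = rng.standard_normal(self.dim) / np.sqrt(self.dim)
        return out


def hash_contextual_stub(text: str, dim: int = 100, window: int = 2) -> np.ndarray:
    """Functional form of :class:`HashContextualStub`."""
    return HashContextualStub(dim=dim, window=window).encode(text)


# ---------------------------------------------------------------------------
# BiLSTM-CRF model


@dataclass
class NeuralConfig:
    """Training configuration; every value is logged with each run.

    ``hidden_size`` is per direction (the concatenated encoder output is
    twice this).  ``batch_size`` 64 matches the contextual-provider path;
    120 is the documented alternative for the static-vector path.
    """

    embedding_dim: int = 100
    hidden_size: int = 100
    epochs: int = 30
    learning_rate: float = 1e-3
    dropout: float = 0.5
    batch_size: int = 64
    max_len: int = 256
    truncate: bool = True
    seed: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class _LstmDirection:
    """One direction's parameters and the caches of one forward pass."""

    def __init__(self, rng: np.random.Generator, d_in: int, h: int):
        s_in = 1.0 / np.sqrt(d_in)
        s_h = 1.0 / np.sqrt(h)
        self.Wx = rng.uniform(-s_in, s_in, (d_in, 4 * h)).astype(np.float32)
        self.Wh = rng.uniform(-s_h, s_h, (h, 4 * h)).astype(np.float32)
        self.b = np.zeros(4 * h, dtype=np.float32)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.h = h

    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """X: (B, T, d_in) → hidden states (B, T, h); caches kept."""
        B, T, _ = X.shape
        h = self.h
        Zin = X @ self.Wx + self.b
        self.X = X
        self.gates = np.empty((B, T, 4 * h), dtype=np.float32)
        self.C = np.empty((B, T, h), dtype=np.float32)
        self.Ct = np.empty((B, T, h), dtype=np.float32)
        self.H = np.empty((B, T, h), dtype=np.float32)
        hp = np.zeros((B, h), dtype=np.float32)
        cp = np.zeros((B, h), dtype=np.float32)
        for t in range(T):
            z = Zin[:, t] + hp @ self.Wh
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            o = _sigmoid(z[:, 2 * h : 3 * h])
            g = np.tanh(z[:, 3 * h :])
            c = f * cp + i * g
            ct = np.tanh(c)
            hv = o * ct
            self.gates[:, t, :h] = i
            self.gates[:, t, h : 2 * h] = f
            self.gates[:, t, 2 * h : 3 * h] = o
            self.gates[:, t, 3 * h :] = g
            self.C[:, t] = c
            self.Ct[:, t] = ct
            self.H[:, t] = hv
            hp, cp = hv, c
        return self.H

    def backward(self, dH: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """dH: (B, T, h) → (dX, [dWx, dWh, db])."""
        B, T, h = dH.shape
        dZ = np.empty((B, T, 4 * h), dtype=np.float32)
        dWh = np.zeros_like(self.Wh)
        dh_next = np.zeros((B, h), dtype=np.float32)
        dc_next = np.zeros((B, h), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            i = self.gates[:, t, :h]
            f = self.gates[:, t, h : 2 * h]
            o = self.gates[:, t, 2 * h : 3 * h]
            g = self.gates[:, t, 3 * h :]
            ct = self.Ct[:, t]
            c_prev = self.C[:, t - 1] if t > 0 else np.zeros((B, h), dtype=np.float32)
            h_prev = self.H[:, t - 1] if t > 0 else np.zeros((B, h), dtype=np.float32)
            dh = dH[:, t] + dh_next
            do = dh * ct
            dc = dh * o * (1.0 - ct * ct) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = dZ[:, t]
            dz[:, :h] = di * i * (1.0 - i)
            dz[:, h : 2 * h] = df * f * (1.0 - f)
            dz[:, 2 * h : 3 * h] = do * o * (1.0 - o)
            dz[:, 3 * h :] = dg * (1.0 - g * g)
            dWh += h_prev.T @ dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        flatZ = dZ.reshape(B * T, 4 * h)
        dWx = self.X.reshape(B * T, -1).T @ flatZ
        db = flatZ.sum(axis=0)
        dX = (flatZ @ self.Wx.T).reshape(self.X.shape)
        return dX, [dWx, dWh, db]


def _reverse_within(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's first ``length`` steps, leaving padding in place."""
    out = np.zeros_like(X)
    for n, L in enumerate(lengths):
        out[n, :L] = X[n, L - 1 :: -1] if L else X[n, :0]
    return out


class BiLstmCrfTagger:
    """BiLSTM encoder + linear projection + CRF output layer.

    ``provider`` is ``"trainable"`` for the jointly learned lookup table,
    or a frozen :class:`StaticVectors` / :class:`HashContextualStub`.
    With a :class:`StaticVectors` provider a single unknown-offset vector
    is learned for out-of-vocabulary characters.
    """

    def __init__(self, config: NeuralConfig | None = None, provider="trainable"):
        self.config = config or NeuralConfig()
        self.provider = provider
        self.epoch_losses_: list[float] = []
        self._fitted = False

    # -- parameter plumbing

    def _init_params(self, vocab: list[str]) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self._rng = rng
        d = cfg.embedding_dim if self.provider == "trainable" else self.provider.dim
        self.input_dim = d
        self.vocab = {ch: i for i, ch in enumerate(vocab)}
        self.params: dict[str, np.ndarray] = {}
        if self.provider == "trainable":
            self.params["E"] = (rng.standard_normal((len(vocab), d)) * 0.1).astype(
                np.float32
            )
        elif isinstance(self.provider, StaticVectors):
            self.params["unk"] = np.zeros(d, dtype=np.float32)
        self.fwd = _LstmDirection(rng, d, cfg.hidden_size)
        self.bwd = _LstmDirection(rng, d, cfg.hidden_size)
        s = 1.0 / np.sqrt(2 * cfg.hidden_size)
        self.params["Wp"] = rng.uniform(-s, s, (2 * cfg.hidden_size, N_TAGS)).astype(
            np.float32
        )
        self.params["bp"] = np.zeros(N_TAGS, dtype=np.float32)
        self.params["trans"] = np.zeros((N_TAGS, N_TAGS), dtype=np.float32)
        for name, arr in zip(("Wxf", "Whf", "bf"), self.fwd.params()):
            self.params[name] = arr
        for name, arr in zip(("Wxb", "Whb", "bb"), self.bwd.params()):
            self.params[name] = arr

    # -- encoding

    def _truncate(self, text: str, tags: Sequence[str] | None = None):
        cfg = self.config
        if len(text) > cfg.max_len:
            if not cfg.truncate:
                raise ValueError(
                    f"sequence length {len(text)} exceeds max_len {cfg.max_len} "
                    "and truncation is disabled"
                )
            text = text[: cfg.max_len]
            tags = list(tags)[: cfg.max_len] if tags is not None else None
        return (text, tags) if tags is not None else text

    def _embed_batch(self, texts: list[str], Tmax: int):
        """Input vectors (B, Tmax, d) plus index/unknown bookkeeping."""
        B = len(texts)
        X = np.zeros((B, Tmax, self.input_dim), dtype=np.float32)
        idx = np.zeros((B, Tmax), dtype=np.intp)
        unk = np.zeros((B, Tmax), dtype=bool)
        for n, text in enumerate(texts):
            if self.provider == "trainable":
                ids = [self.vocab.get(ch, self.vocab[UNK_TOKEN]) for ch in text]
                idx[n, : len(text)] = ids
                X[n, : len(text)] = self.params["E"][ids]
            else:
                X[n, : len(text)] = self.provider.encode(text)
                if isinstance(self.provider, StaticVectors):
                    m = self.provider.unknown_mask(text)
                    unk[n, : len(text)] = m
                    X[n, : len(text)][m] += self.params["unk"]
        return X, idx, unk

    def _encode_batch(self, X: np.ndarray, lengths: np.ndarray, train: bool):
        Hf = self.fwd.forward(X)
        Xr = _reverse_within(X, lengths)
        Hb = _reverse_within(self.bwd.forward(Xr), lengths)
        H = np.concatenate([Hf, Hb], axis=2)
        if train and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            self._drop_mask = (
                self._rng.random(H.shape, dtype=np.float32) < keep
            ).astype(np.float32) / keep
            H = H * self._drop_mask
        else:
            self._drop_mask = None
        self._H = H
        emissions = H @ self.params["Wp"] + self.params["bp"]
        return emissions.astype(np.float64)

    def _backward_batch(self, d_em: np.ndarray, X, idx, unk, lengths):
        """Gradients for one batch given d loss / d emissions."""
        cfg = self.config
        B, T, _ = d_em.shape
        dE = d_em.astype(np.float32)
        flat_dE = dE.reshape(B * T, N_TAGS)
        grads = {
            "Wp": self._H.reshape(B * T, -1).T @ flat_dE,
            "bp": flat_dE.sum(axis=0),
        }
        dH = dE @ self.params["Wp"].T
        if self._drop_mask is not None:
            dH = dH * self._drop_mask
        h = cfg.hidden_size
        dXf, gf = self.fwd.backward(np.ascontiguousarray(dH[:, :, :h]))
        dHb = _reverse_within(np.ascontiguousarray(dH[:, :, h:]), lengths)
        dXr, gb = self.bwd.backward(dHb)
        dX = dXf + _reverse_within(dXr, lengths)
        for name, g in zip(("Wxf", "Whf", "bf"), gf):
            grads[name] = g
        for name, g in zip(("Wxb", "Whb", "bb"), gb):
            grads[name] = g
        if self.provider == "trainable":
            dEmb = np.zeros_like(self.params["E"])
            np.add.at(dEmb, idx.ravel(), dX.reshape(B * T, -1))
            grads["E"] = dEmb
        elif isinstance(self.provider, StaticVectors):
            grads["unk"] = dX[unk].sum(axis=0)
        return grads

    # -- training

    def fit(
        self, pairs: Sequence[tuple[str, Sequence[str]]], verbose: bool = False
    ) -> "BiLstmCrfTagger":
        cfg = self.config
        if not pairs:
            raise ValueError("empty training set")
        clean: list[tuple[str, list[str]]] = []
        for i, (text, tags) in enumerate(pairs):
            if len(text) != len(tags):
                raise ValueError(f"pair {i}: text/tags length mismatch")
            bad = validate_tags(tags)
            if bad:
                raise ValueError(f"pair {i}: illegal gold tag at position {bad[0]}")
            if len(text) == 0:
                continue
            clean.append(self._truncate(text, tags))
        vocab = [UNK_TOKEN] + sorted({ch for text, _ in clean for ch in text})
        self._init_params(vocab)

        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        step = 0
        b1, b2, eps = 0.9, 0.999, 1e-8

        # length-bucketed batches, batch order reshuffled each epoch
        order = sorted(range(len(clean)), key=lambda i: (len(clean[i][0]), i))
        batches = [
            order[i : i + cfg.batch_size] for i in range(0, len(order), cfg.batch_size)
        ]
        self.epoch_losses_ = []
        n_chars_total = sum(len(t) for t, _ in clean)
        for epoch in range(cfg.epochs):
            self._rng.shuffle(batches)
            total_nll = 0.0
            for batch in batches:
                texts = [clean[i][0] for i in batch]
                lengths = np.array([len(t) for t in texts])
                T = int(lengths.max())
                mask = np.arange(T)[None, :] < lengths[:, None]
                gold = np.zeros((len(batch), T), dtype=np.intp)
                for n, i in enumerate(batch):
                    gold[n, : lengths[n]] = [TAG_TO_INDEX[t] for t in clean[i][1]]
                X, idx, unk = self._embed_batch(texts, T)
                emissions = self._encode_batch(X, lengths, train=True)
                nll, d_em, d_trans = crf_nll_and_grads(
                    emissions, mask, gold, self.params["trans"].astype(np.float64)
                )
                total_nll += nll
                scale = 1.0 / mask.sum()  # per-character loss
                grads = self._backward_batch(d_em * scale, X, idx, unk, lengths)
                grads["trans"] = (d_trans * scale).astype(np.float32)
                step += 1
                for k, g in grads.items():
                    g = g.astype(np.float32)
                    adam_m[k] = b1 * adam_m[k] + (1 - b1) * g
                    adam_v[k] = b2 * adam_v[k] + (1 - b2) * g * g
                    mhat = adam_m[k] / (1 - b1**step)
                    vhat = adam_v[k] / (1 - b2**step)
                    self.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
                # _LstmDirection holds views of params; refresh after update
                self.fwd.Wx, self.fwd.Wh, self.fwd.b = (
                    self.params["Wxf"],
                    self.params["Whf"],
                    self.params["bf"],
                )
                self.bwd.Wx, self.bwd.Wh, self.bwd.b = (
                    self.params["Wxb"],
                    self.params["Whb"],
                    self.params["bb"],
                )
            self.epoch_losses_.append(total_nll / n_chars_total)
            if verbose:
                print(f"  epoch {epoch + 1}/{cfg.epochs}: loss {self.epoch_losses_[-1]:.4f}")
        self._fitted = True
        return self

    # -- prediction

    def emissions_for(self, text: str) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("tagger is not fitted")
        text = self._truncate(text)
        if len(text) == 0:
            return np.zeros((0, N_TAGS))
        X, _, _ = self._embed_batch([text], len(text))
        return self._encode_batch(X, np.array([len(text)]), train=False)[0]

    def predict_tags(self, text: str) -> list[str]:
        """Viterbi decode over neural emissions; orphan-I repair applied.

        Text longer than ``max_len`` is truncated and the tail tagged O
        (evaluation masks truncated tails symmetrically).
        """
        if not self._fitted:
            raise RuntimeError("tagger is not fitted")
        full_len = len(text)
        text = self._truncate(text)
        if len(text) == 0:
            return ["O"] * full_len
        path, _ = viterbi_decode(
            self.emissions_for(text), self.params["trans"].astype(np.float64)
        )
        tags = repair_orphan_i([TAGS[i] for i in path])
        return tags + ["O"] * (full_len - len(tags))

    def predict_corpus(self, texts: Sequence[str]) -> list[list[str]]:
        return [self.predict_tags(t) for t in texts]

    # -- checkpoint format

    FORMAT_VERSION = 1

    def save(self, path: str | Path) -> None:
        if not self._fitted:
            raise RuntimeError("tagger is not fitted")
        if self.provider != "trainable":
            raise ValueError("only trainable-lookup models are checkpointable")
        obj = {
            "format": "hepanlp-bilstm-crf",
            "version": self.FORMAT_VERSION,
            "config": vars(self.config),
            "vocab": sorted(self.vocab, key=self.vocab.get),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, ensure_ascii=False)

    @classmethod
    def load(cls, path: str | Path) -> "BiLstmCrfTagger":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        if obj.get("format") != "hepanlp-bilstm-crf" or obj.get("version") != cls.FORMAT_VERSION:
            raise ValueError(f"{path}: not a supported checkpoint")
        model = cls(NeuralConfig(**obj["config"]))
        model._init_params(obj["vocab"])
        for k, v in obj["params"].items():
            model.params[k] = np.asarray(v, dtype=np.float32)
        model.fwd.Wx, model.fwd.Wh, model.fwd.b = (
            model.params["Wxf"],
            model.params["Whf"],
            model.params["bf"],
        )
        model.bwd.Wx, model.bwd.Wh, model.bwd.b = (
            model.params["Wxb"],
            model.params["Whb"],
            model.params["bb"],
        )
        model._fitted = True
        return model


def fit_neural(
    pairs: Sequence[tuple[str, Sequence[str]]],
    config: NeuralConfig | None = None,
    provider="trainable",
    verbose: bool = False,
) -> BiLstmCrfTagger:
    """Convenience constructor mirroring :func:`hepanlp.crf.fit_crf`."""
    return BiLstmCrfTagger(config, provider).fit(pairs, verbose=verbose)
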