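"""Linear-chain CRF over the 5-tag BIO space.

This module is the inference and training core shared by the two
labelers: the feature-based :class:`CrfTagger` scores each character from
hand-crafted window features, while the BiLSTM tagger feeds neural
emission scores through the same :func:`log_forward` / :func:`viterbi_decode`
machinery.

Scores are unnormalized log-potentials: the score of a tag sequence
``y_1..y_T`` is ``Σ_t emissions[t, y_t] + Σ_t transitions[y_{t-1}, y_t]``.
The conditional probability of a sequence is its exponentiated score
divided by the partition function; :func:`log_forward` computes the log
partition exactly by dynamic programming, in log space for stability.
Begin/end effects are carried by sentinel features rather than explicit
start/stop transition vectors.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.sparse

from .tagging import N_TAGS, TAGS, TAG_TO_INDEX, repair_orphan_i, validate_tags

# ---------------------------------------------------------------------------
# Exact inference (single sequence)


def log_forward(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """Log partition: log Σ over all tag sequences of exp(score).

    ``emissions`` is (T, K), ``transitions`` (K, K); T ≥ 1.
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be (T, K) with T >= 1")
    alpha = emissions[0].copy()
    for t in range(1, emissions.shape[0]):
        m = alpha.max()
        alpha = m + np.log(np.exp(alpha - m) @ np.exp(transitions)) + emissions[t]
    m = alpha.max()
    return float(m + np.log(np.exp(alpha - m).sum()))


def viterbi_decode(
    emissions: np.ndarray, transitions: np.ndarray
) -> tuple[list[int], float]:
    """Highest-scoring tag index sequence and its score.

    Ties are broken toward the lowest tag index at each backtracking
    step, so decoding is deterministic.
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be (T, K) with T >= 1")
    T, K = emissions.shape
    delta = emissions[0].copy()
    back = np.zeros((T, K), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + transitions  # (prev, cur)
        back[t] = np.argmax(cand, axis=0)  # argmax returns lowest index on ties
        delta = cand[back[t], np.arange(K)] + emissions[t]
    best_last = int(np.argmax(delta))
    score = float(delta[best_last])
    path = [best_last]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, score


# ---------------------------------------------------------------------------
# Batched forward-backward (training workhorse)


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def crf_nll_and_grads(
    emissions: np.ndarray,
    mask: np.ndarray,
    gold: np.ndarray,
    transitions: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Total negative conditional log-likelihood and its gradients.

    Parameters are batched and right-padded: ``emissions`` (N, T, K),
    ``mask`` (N, T) boolean with at least one valid step per row,
    ``gold`` (N, T) integer tag indices (arbitrary at padded steps).

    Returns ``(nll, d_emissions, d_transitions)`` where the gradients are
    of the NLL (expected minus observed sufficient statistics).  Shared by
    the feature-based and neural labelers.
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    N, T, K = emissions.shape
    maskf = mask.astype(np.float64)
    em = emissions * maskf[:, :, None]  # zero pad positions

    alpha = np.empty((N, T, K))
    alpha[:, 0] = em[:, 0]
    for t in range(1, T):
        prev = alpha[:, t - 1]
        cand = _logsumexp(prev[:, :, None] + transitions[None], axis=1) + em[:, t]
        alpha[:, t] = np.where(mask[:, t, None], cand, prev)
    logZ = _logsumexp(alpha[:, -1], axis=1)

    beta = np.zeros((N, T, K))
    for t in range(T - 2, -1, -1):
        nxt = em[:, t + 1] + beta[:, t + 1]
        cand = _logsumexp(transitions[None] + nxt[:, None, :], axis=2)
        beta[:, t] = np.where(mask[:, t + 1, None], cand, 0.0)

    # node marginals minus observed indicators
    marg = np.exp(alpha + beta - logZ[:, None, None]) * maskf[:, :, None]
    d_em = marg.copy()
    rows = np.repeat(np.arange(N), T)
    cols = np.tile(np.arange(T), N)
    d_em[rows, cols, gold.ravel()] -= maskf.ravel()

    # edge marginals minus observed bigram counts
    d_trans = np.zeros((K, K))
    for t in range(1, T):
        lp = (
            alpha[:, t - 1, :, None]
            + transitions[None]
            + (em[:, t] + beta[:, t])[:, None, :]
            - logZ[:, None, None]
        )
        d_trans += (np.exp(lp) * maskf[:, t, None, None]).sum(axis=0)
        both = mask[:, t]
        np.add.at(d_trans, (gold[both, t - 1], gold[both, t]), -1.0)

    gold_em = em[rows, cols, gold.ravel()].reshape(N, T)
    gold_score = gold_em.sum(axis=1)
    for t in range(1, T):
        both = mask[:, t]
        gold_score[both] += transitions[gold[both, t - 1], gold[both, t]]
    nll = float(logZ.sum() - gold_score.sum())
    return nll, d_em, d_trans


def batched_viterbi(
    emissions: np.ndarray, mask: np.ndarray, transitions: np.ndarray
) -> list[list[int]]:
    """Viterbi decode each row of a right-padded batch."""
    out = []
    lengths = mask.sum(axis=1).astype(int)
    for n, L in enumerate(lengths):
        if L == 0:
            out.append([])
        else:
            out.append(viterbi_decode(emissions[n, :L], transitions)[0])
    return out


# ---------------------------------------------------------------------------
# Character window features

_SENTINEL_L = "<s>"
_SENTINEL_R = "</s>"


def _char_class(ch: str) -> str:
    if ch.isdigit():
        return "digit"
    if ("a" <= ch <= "z") or ("A" <= ch <= "Z"):
        return "latin"
    if unicodedata.category(ch).startswith("P"):
        return "punct"
    return "other"


def extract_features(text: str, position: int) -> list[str]:
    """Deterministic window features for one character position.

    Current char, chars at offsets ±1/±2, the two bigrams touching the
    position, and a character-class flag; sentinels pad the boundaries so
    the feature count per position is constant (8).
    """
    if not (0 <= position < len(text)):
        raise IndexError(f"position {position} out of range")

    def at(i: int) -> str:
        if i < 0:
            return _SENTINEL_L
        if i >= len(text):
            return _SENTINEL_R
        return text[i]

    c = text[position]
    return [
        f"w0={c}",
        f"w-1={at(position - 1)}",
        f"w+1={at(position + 1)}",
        f"w-2={at(position - 2)}",
        f"w+2={at(position + 2)}",
        f"b-1={at(position - 1)}|{c}",
        f"b+1={c}|{at(position + 1)}",
        f"cls={_char_class(c)}",
    ]


FEATURE_TEMPLATE_ID = "char-window-v1"


# ---------------------------------------------------------------------------
# Feature-based CRF tagger


@dataclass
class CrfTagger:
    """Linear-chain CRF with window features, trained by maximizing the
    L2-regularized conditional log-likelihood with L-BFGS.

    The gradient of the log-likelihood is the observed minus expected
    feature counts, the latter from forward-backward marginals; training
    is deterministic given the data and settings.
    """

    l2_strength: float = 0.1
    max_iterations: int = 200
    tolerance: float = 1e-6
    feature_template: str = FEATURE_TEMPLATE_ID

    feature_index: dict[str, int] = field(default_factory=dict, repr=False)
    weights: np.ndarray | None = field(default=None, repr=False)  # (F, K)
    transitions: np.ndarray | None = field(default=None, repr=False)  # (K, K)
    objective_trace_: list[float] = field(default_factory=list, repr=False)

    # -- feature matrix assembly

    def _build_rows(
        self, texts: Sequence[str], max_len: int, freeze: bool
    ) -> scipy.sparse.csr_matrix:
        """Sparse indicator matrix over (sequence, position) rows."""
        indptr = [0]
        indices: list[int] = []
        for text in texts:
            for t in range(max_len):
                if t < len(text):
                    for f in extract_features(text, t):
                        idx = self.feature_index.get(f)
                        if idx is None and not freeze:
                            idx = len(self.feature_index)
                            self.feature_index[f] = idx
                        if idx is not None:
                            indices.append(idx)
                indptr.append(len(indices))
        data = np.ones(len(indices), dtype=np.float64)
        n_feat = max(len(self.feature_index), 1)
        return scipy.sparse.csr_matrix(
            (data, indices, indptr), shape=(len(texts) * max_len, n_feat)
        )

    # -- training

    def fit(
        self, pairs: Sequence[tuple[str, Sequence[str]]], verbose: bool = False
    ) -> "CrfTagger":
        if not pairs:
            raise ValueError("empty training set")
        for i, (text, tags) in enumerate(pairs):
            if len(text) != len(tags):
                raise ValueError(f"pair {i}: text/tags length mismatch")
            bad = validate_tags(tags)
            if bad:
                raise ValueError(f"pair {i}: illegal gold tag at position {bad[0]}")
        pairs = [(t, g) for t, g in pairs if len(t) > 0]
        texts = [t for t, _ in pairs]
        N = len(texts)
        T = max(len(t) for t in texts)
        K = N_TAGS

        self.feature_index = {}
        X = self._build_rows(texts, T, freeze=False)
        F = len(self.feature_index)
        X.resize((N * T, F))

        mask = np.zeros((N, T), dtype=bool)
        gold = np.zeros((N, T), dtype=np.intp)
        for n, (text, tags) in enumerate(pairs):
            mask[n, : len(text)] = True
            gold[n, : len(text)] = [TAG_TO_INDEX[t] for t in tags]

        self.objective_trace_ = []

        def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
            W = params[: F * K].reshape(F, K)
            trans = params[F * K :].reshape(K, K)
            emissions = (X @ W).reshape(N, T, K)
            nll, d_em, d_trans = crf_nll_and_grads(emissions, mask, gold, trans)
            dW = (X.T @ d_em.reshape(N * T, K)).reshape(F, K)
            obj = nll + self.l2_strength * (np.sum(W * W) + np.sum(trans * trans))
            grad = np.concatenate(
                [
                    (dW + 2.0 * self.l2_strength * W).ravel(),
                    (d_trans + 2.0 * self.l2_strength * trans).ravel(),
                ]
            )
            return obj, grad

        def cb(params: np.ndarray) -> None:
            val = objective(params)[0]
            self.objective_trace_.append(val)
            if verbose:
                print(f"  crf iter {len(self.objective_trace_)}: obj {val:.4f}")

        x0 = np.zeros(F * K + K * K)
        res = scipy.optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={
                "maxiter": self.max_iterations,
                "ftol": self.tolerance,
                "gtol": 1e-6,
            },
        )
        self.weights = res.x[: F * K].reshape(F, K)
        self.transitions = res.x[F * K :].reshape(K, K)
        return self

    # -- prediction

    def emissions_for(self, text: str) -> np.ndarray:
        if self.weights is None:
            raise RuntimeError("tagger is not fitted")
        if len(text) == 0:
            return np.zeros((0, N_TAGS))
        self_backup = self.feature_index
        X = self._build_rows([text], len(text), freeze=True)
        self.feature_index = self_backup
        X.resize((len(text), self.weights.shape[0]))
        return X @ self.weights

    def predict_tags(self, text: str) -> list[str]:
        """Viterbi decode; output passes BIO legality after orphan-I repair."""
        if len(text) == 0:
            return []
        path, _ = viterbi_decode(self.emissions_for(text), self.transitions)
        return repair_orphan_i([TAGS[i] for i in path])

    def predict_corpus(self, texts: Sequence[str]) -> list[list[str]]:
        return [self.predict_tags(t) for t in texts]

    # -- serialization

    FORMAT_VERSION = 1

    def save(self, path: str | Path) -> None:
        if self.weights is None:
            raise RuntimeError("tagger is not fitted")
        obj = {
            "format": "hepanlp-crf",
            "version": self.FORMAT_VERSION,
            "feature_template": self.feature_template,
            "l2_strength": self.l2_strength,
            "tags": list(TAGS),
            "feature_index": self.feature_index,
            "weights": self.weights.tolist(),
            "transitions": self.transitions.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, ensure_ascii=False)

    @classmethod
    def load(cls, path: str | Path) -> "CrfTagger":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        if obj.get("format") != "hepanlp-crf" or obj.get("version") != cls.FORMAT_VERSION:
            raise ValueError(f"{path}: not a supported CRF model file")
        tagger = cls(l2_strength=obj["l2_strength"], feature_template=obj["feature_template"])
        tagger.feature_index = {k: int(v) for k, v in obj["feature_index"].items()}
        tagger.weights = np.asarray(obj["weights"], dtype=np.float64)
        tagger.transitions = np.asarray(obj["transitions"], dtype=np.float64)
        return tagger


def fit_crf(
    pairs: Sequence[tuple[str, Sequence[str]]],
    l2_strength: float = 0.1,
    max_iterations: int = 200,
    tolerance: float = 1e-6,
) -> CrfTagger:
    """Convenience constructor: fit a :class:`CrfTagger` on (text, tags) pairs."""
    return CrfTagger(
        l2_strength=l2_strength, max_iterations=max_iterations, tolerance=tolerance
    ).fit(pairs)
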