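"""Exact CRF inference against enumeration, training gradients, fitting."""

import itertools

import numpy as np
import pytest

from hepanlp.crf import (
    CrfTagger,
    crf_nll_and_grads,
    extract_features,
    fit_crf,
    log_forward,
    viterbi_decode,
)
from hepanlp.tagging import N_TAGS, TAGS


def enumerate_scores(emissions, transitions):
    """Score every tag sequence explicitly (oracle for T ≤ 6)."""
    T = emissions.shape[0]
    scores = []
    for seq in itertools.product(range(N_TAGS), repeat=T):
        s = sum(emissions[t, y] for t, y in enumerate(seq))
        s += sum(transitions[a, b] for a, b in zip(seq, seq[1:]))
        scores.append(s)
    return np.array(scores)


def test_log_forward_uniform_and_single_step():
    zeros = np.zeros((3, N_TAGS))
    assert log_forward(zeros, np.zeros((N_TAGS, N_TAGS))) == pytest.approx(3 * np.log(5))
    em = np.random.default_rng(0).normal(size=(1, N_TAGS))
    expected = np.log(np.exp(em[0]).sum())
    assert log_forward(em, np.zeros((N_TAGS, N_TAGS))) == pytest.approx(expected)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        log_forward(np.zeros((0, N_TAGS)), np.zeros((N_TAGS, N_TAGS)))
    with pytest.raises(ValueError):
        viterbi_decode(np.zeros((0, N_TAGS)), np.zeros((N_TAGS, N_TAGS)))


def test_inference_matches_enumeration_small():
    rng = np.random.default_rng(42)
    for _ in range(25):
        T = int(rng.integers(1, 5))
        em = rng.normal(size=(T, N_TAGS)) * 2
        tr = rng.normal(size=(N_TAGS, N_TAGS)) * 2
        scores = enumerate_scores(em, tr)
        m = scores.max()
        assert log_forward(em, tr) == pytest.approx(m + np.log(np.exp(scores - m).sum()), abs=1e-8)
        path, sc = viterbi_decode(em, tr)
        assert sc == pytest.approx(scores.max(), abs=1e-8)
        # partition dominates the maximum
        assert log_forward(em, tr) >= sc


def test_shift_invariance_of_log_partition():
    rng = np.random.default_rng(5)
    em = rng.normal(size=(4, N_TAGS))
    tr = rng.normal(size=(N_TAGS, N_TAGS))
    base = log_forward(em, tr)
    shifted = em.copy()
    shifted[2] += 3.7
    assert log_forward(shifted, tr) == pytest.approx(base + 3.7)


def test_viterbi_tie_breaks_to_lowest_tag_index():
    # fully symmetric: every sequence scores 0; rule picks index 0 throughout
    path, score = viterbi_decode(np.zeros((3, N_TAGS)), np.zeros((N_TAGS, N_TAGS)))
    assert path == [0, 0, 0] and score == 0.0
    # two-way tie between tags 1 and 3 at the last step
    em = np.zeros((2, N_TAGS))
    em[1, 1] = em[1, 3] = 5.0
    path, _ = viterbi_decode(em, np.zeros((N_TAGS, N_TAGS)))
    assert path[1] == 1


def test_nll_gradients_match_central_finite_differences():
    rng = np.random.default_rng(9)
    text = "动脉期"
    feats = [extract_features(text, i) for i in range(3)]
    vocab = sorted({f for fs in feats for f in fs})
    X = np.zeros((3, len(vocab)))
    for i, fs in enumerate(feats):
        for f in fs:
            X[i, vocab.index(f)] = 1.0
    W = rng.normal(size=(len(vocab), N_TAGS)) * 0.3
    trans = rng.normal(size=(N_TAGS, N_TAGS)) * 0.3
    gold = np.array([[0, 1, 4]])
    mask = np.ones((1, 3), dtype=bool)

    def nll(Wv, tv):
        em = (X @ Wv).reshape(1, 3, N_TAGS)
        return crf_nll_and_grads(em, mask, gold, tv)[0]

    base_em = (X @ W).reshape(1, 3, N_TAGS)
    _, d_em, d_tr = crf_nll_and_grads(base_em, mask, gold, trans)
    dW = X.T @ d_em[0]
    eps = 1e-6
    for i, j in [(0, 2), (3, 1), (5, 4), (1, 0)]:
        Wp, Wm = W.copy(), W.copy()
        Wp[i, j] += eps
        Wm[i, j] -= eps
        fd = (nll(Wp, trans) - nll(Wm, trans)) / (2 * eps)
        assert abs(fd - dW[i, j]) <= 1e-5 * max(1.0, abs(fd))
    for a, b in [(0, 0), (1, 4), (4, 2)]:
        tp, tm = trans.copy(), trans.copy()
        tp[a, b] += eps
        tm[a, b] -= eps
        fd = (nll(W, tp) - nll(W, tm)) / (2 * eps)
        assert abs(fd - d_tr[a, b]) <= 1e-5 * max(1.0, abs(fd))


def test_feature_extraction_templates():
    feats = extract_features("快进", 0)
    assert "w0=快" in feats and "w+1=进" in feats and "w-1=<s>" in feats
    assert len(extract_features("字", 0)) == len(extract_features("动脉期强化", 2)) == 8
    assert "cls=digit" in extract_features("85", 0)
    assert "cls=latin" in extract_features("CT", 1)


def test_fit_memorizes_single_pair_and_objective_decreases():
    pair = ("动脉期强化明显好", ["B-APHE", "I-APHE", "I-APHE", "I-APHE", "I-APHE", "I-APHE", "O", "O"])
    tagger = fit_crf([pair], max_iterations=80)
    assert tagger.predict_tags(pair[0]) == pair[1]
    trace = tagger.objective_trace_
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))


def test_fit_rejects_illegal_gold():
    with pytest.raises(ValueError, match="illegal gold"):
        fit_crf([("ab", ["O", "I-APHE"])])


def test_predict_empty_text():
    tagger = fit_crf([("快进", ["B-APHE", "I-APHE"])], max_iterations=20)
    assert tagger.predict_tags("") == []


def test_save_load_roundtrip(tmp_path):
    pairs = [
        ("动脉期强化明显", ["B-APHE"] + ["I-APHE"] * 6),
        ("未见异常", ["O"] * 4),
    ]
    tagger = fit_crf(pairs, max_iterations=60)
    path = tmp_path / "crf.json"
    tagger.save(path)
    loaded = CrfTagger.load(path)
    for text in ["动脉期强化明显", "未见异常", "新的句子"]:
        assert loaded.predict_tags(text) == tagger.predict_tags(text)
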