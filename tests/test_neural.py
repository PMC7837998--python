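"""Embedding providers and the BiLSTM-CRF labeler."""

import numpy as np
import pytest

from hepanlp.neural import (
    BiLstmCrfTagger,
    HashContextualStub,
    NeuralConfig,
    StaticVectors,
    fit_neural,
    load_pretrained_vectors,
    write_vectors,
)

TOY_PAIRS = [
    ("动脉期强化明显。", ["B-APHE"] + ["I-APHE"] * 6 + ["O"]),
    ("门脉期相对低密度。", ["B-PDPH"] + ["I-PDPH"] * 7 + ["O"]),
    ("增强呈快进表现。", ["O", "O", "O", "B-APHE", "I-APHE", "O", "O", "O"]),
    ("未见异常强化灶。", ["O"] * 8),
    ("肝脏形态未见异常。", ["O"] * 9),
]

FAST = NeuralConfig(epochs=200, seed=3, hidden_size=24, embedding_dim=16, batch_size=2)


def test_load_pretrained_vectors_with_header(tmp_path):
    path = tmp_path / "vec.txt"
    path.write_text("2 3\n肝 0.1 0.2 0.3\n脏 -1.0 0.0 1.0\n", encoding="utf-8")
    vec = load_pretrained_vectors(path)
    assert vec.dim == 3
    np.testing.assert_allclose(vec.encode("肝")[0], [0.1, 0.2, 0.3], rtol=1e-6)
    np.testing.assert_allclose(vec.encode("脏")[0], [-1.0, 0.0, 1.0], rtol=1e-6)
    # unknown characters map to the zero vector and are flagged
    np.testing.assert_array_equal(vec.encode("胆")[0], np.zeros(3))
    np.testing.assert_array_equal(vec.unknown_mask("肝胆"), [False, True])


def test_load_pretrained_vectors_dimension_error(tmp_path):
    path = tmp_path / "vec.txt"
    path.write_text("肝 0.1 0.2\n脏 1.0 2.0 3.0\n", encoding="utf-8")
    with pytest.raises(ValueError, match=":2"):
        load_pretrained_vectors(path)


def test_vector_table_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    table = {ch: rng.normal(size=5).astype(np.float32) for ch in "肝脏胆脾胃"}
    path = tmp_path / "t.txt"
    write_vectors(path, table)
    back = load_pretrained_vectors(path)
    assert set(back.table) == set(table)
    for ch in table:
        np.testing.assert_allclose(back.table[ch], table[ch], rtol=1e-6)


def test_hash_stub_is_contextual_and_deterministic():
    stub = HashContextualStub(dim=16)
    a = stub.encode("强化明显")
    b = stub.encode("未见强化")
    # same character 强, different neighbors -> different vectors
    assert not np.allclose(a[0], b[2])
    # identical sequences -> identical outputs (cosine exactly 1)
    c = stub.encode("强化明显")
    np.testing.assert_array_equal(a, c)
    cos = a[0] @ c[0] / (np.linalg.norm(a[0]) * np.linalg.norm(c[0]))
    assert cos == pytest.approx(1.0)
    with pytest.raises(ValueError):
        HashContextualStub(max_len=4).encode("太长的序列了")


def test_toy_memorization_reaches_full_train_accuracy():
    model = fit_neural(TOY_PAIRS, FAST)
    correct = total = 0
    for text, gold in TOY_PAIRS:
        pred = model.predict_tags(text)
        correct += sum(p == g for p, g in zip(pred, gold))
        total += len(gold)
    assert correct == total
    assert model.epoch_losses_[9] < model.epoch_losses_[0]


def test_same_seed_reproduces_final_loss_exactly():
    cfg = NeuralConfig(epochs=6, seed=11, hidden_size=16, embedding_dim=12, batch_size=3)
    m1 = fit_neural(TOY_PAIRS, cfg)
    m2 = fit_neural(TOY_PAIRS, cfg)
    assert m1.epoch_losses_[-1] == pytest.approx(m2.epoch_losses_[-1], abs=1e-6)
    assert m1.predict_tags("动脉期强化明显。") == m2.predict_tags("动脉期强化明显。")


def test_truncation_policy():
    cfg = NeuralConfig(epochs=2, seed=0, hidden_size=8, embedding_dim=8, max_len=6)
    model = fit_neural([(t[:6], g[:6]) for t, g in TOY_PAIRS], cfg)
    long_text = "动脉期强化明显好好好"
    pred = model.predict_tags(long_text)
    assert len(pred) == len(long_text)
    assert pred[6:] == ["O"] * 4  # truncated tail scored O
    strict = NeuralConfig(epochs=1, seed=0, max_len=6, truncate=False)
    with pytest.raises(ValueError, match="max_len"):
        fit_neural(TOY_PAIRS, strict)


def test_empty_text_prediction():
    model = fit_neural(TOY_PAIRS[:2], NeuralConfig(epochs=2, seed=0, hidden_size=8, embedding_dim=8))
    assert model.predict_tags("") == []


@pytest.mark.parametrize("provider_kind", ["static", "stub"])
def test_frozen_provider_paths_train(provider_kind):
    if provider_kind == "static":
        rng = np.random.default_rng(2)
        chars = sorted({ch for t, _ in TOY_PAIRS for ch in t})[:-2]  # leave OOV
        provider = StaticVectors(
            {ch: rng.normal(size=12).astype(np.float32) for ch in chars}, 12
        )
    else:
        provider = HashContextualStub(dim=12)
    cfg = NeuralConfig(epochs=25, seed=5, hidden_size=24, batch_size=4)
    model = fit_neural(TOY_PAIRS, cfg, provider=provider)
    assert model.epoch_losses_[-1] < model.epoch_losses_[0]
    pred = model.predict_tags("动脉期强化明显。")
    assert len(pred) == 8


def test_checkpoint_roundtrip(tmp_path):
    model = fit_neural(TOY_PAIRS, FAST)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = BiLstmCrfTagger.load(path)
    for text, _ in TOY_PAIRS:
        assert loaded.predict_tags(text) == model.predict_tags(text)
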