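"""Determinism, planted statistics and annotation legality of the generator."""

import io

import numpy as np
import pytest
from scipy import stats

from hepanlp.corpus import write_reports_jsonl
from hepanlp.fenlp import features_for_corpus
from hepanlp.synth import (
    DEFAULT_FEATURE_PREVALENCES,
    GeneratorConfig,
    PLANTED_FEATURE_KEYS,
    default_lexicon,
    generate_corpus,
    phrase_bank,
)
from hepanlp.tagging import tags_to_spans, validate_tags


def serialize(corpus) -> bytes:
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "c.jsonl"
        write_reports_jsonl(p, corpus)
        return p.read_bytes()


def test_same_seed_same_bytes_different_seed_differs():
    cfg = GeneratorConfig(seed=4, n_cancer=30, n_noncancer=40)
    assert serialize(generate_corpus(cfg)) == serialize(generate_corpus(cfg))
    other = GeneratorConfig(seed=5, n_cancer=30, n_noncancer=40)
    assert serialize(generate_corpus(cfg)) != serialize(generate_corpus(other))


def test_degenerate_probabilities_force_flags():
    cfg = GeneratorConfig(
        seed=1,
        n_cancer=2,
        n_noncancer=2,
        p_aphe_given_cancer=1.0,
        p_aphe_given_noncancer=0.0,
        p_pdph_given_cancer=0.0,
        p_pdph_given_noncancer=0.0,
        feature_prevalences={},
    )
    corpus = generate_corpus(cfg)
    flagged = [r for r in corpus if r.evidence_flags[0]]
    assert len(flagged) == 2
    assert all(r.diagnosis == 1 for r in flagged)
    assert all(r.evidence_flags[1] == 0 for r in corpus)


def test_invalid_probability_rejected():
    with pytest.raises(ValueError, match="probabilities"):
        GeneratorConfig(p_abbreviation=1.5).validate()
    with pytest.raises(ValueError, match="non-negative"):
        GeneratorConfig(n_cancer=-1).validate()


def test_gold_tags_legal_and_reports_within_length_bounds():
    corpus = generate_corpus(GeneratorConfig(seed=2, n_cancer=60, n_noncancer=60))
    for r in corpus:
        assert validate_tags(r.gold_tags) == []
        n_sentences = r.text.count("。")
        assert 3 <= n_sentences <= 10
        # flags consistent with the presence of a generated mention
        spans = tags_to_spans(r.text, r.gold_tags)
        has = {"APHE": 0, "PDPH": 0}
        for s in spans:
            has[s.entity_type] = 1
        abbrev = {"APHE": "快进" in r.text, "PDPH": "快出" in r.text}
        assert r.evidence_flags == (
            max(has["APHE"], abbrev["APHE"]),
            max(has["PDPH"], abbrev["PDPH"]),
        )


def test_phrase_bank_contents_and_legality():
    bank = phrase_bank()
    surfaces = {text: ent for text, ent, _ in bank}
    assert surfaces["门脉期相对低密度"] == "PDPH"
    assert surfaces["动脉期强化明显"] == "APHE"
    assert surfaces["快进"] == "APHE" and surfaces["快出"] == "PDPH"
    for text, ent, (start, end) in bank:
        tags = ["O"] * len(text)
        tags[start] = f"B-{ent}"
        for i in range(start + 1, end):
            tags[i] = f"I-{ent}"
        spans = tags_to_spans(text, tags)
        assert [(s.entity_type, s.start, s.end) for s in spans] == [(ent, start, end)]


def test_report_level_aphe_count_near_study_marginal():
    corpus = generate_corpus(GeneratorConfig(seed=0))
    aphe = sum(r.evidence_flags[0] for r in corpus)
    pdph = sum(r.evidence_flags[1] for r in corpus)
    # 99% normal interval around the emulated marginal counts (602, 330)
    var_a = 480 * (442 / 480) * (1 - 442 / 480) + 609 * (160 / 609) * (1 - 160 / 609)
    assert abs(aphe - 602) < 2.576 * np.sqrt(var_a)
    var_p = 480 * (330 / 480) * (1 - 330 / 480)
    assert abs(pdph - 330) < 2.576 * np.sqrt(var_p)
    assert all(r.evidence_flags[1] == 0 for r in corpus if r.diagnosis == 0)


def test_class_conditional_feature_frequencies_converge():
    """Planted feature prevalences pass a goodness-of-fit check at n≥5000."""
    cfg = GeneratorConfig(seed=12345, n_cancer=2500, n_noncancer=2500)
    corpus = generate_corpus(cfg)
    lexicon = default_lexicon()
    feats = features_for_corpus(corpus, lexicon)
    for fid, (p1, p0) in DEFAULT_FEATURE_PREVALENCES.items():
        key = PLANTED_FEATURE_KEYS[fid][0]
        for label, p in ((1, p1), (0, p0)):
            group = [r for r in corpus if r.diagnosis == label]
            hits = sum(any(f.key == key for f in feats[r.report_id]) for r in group)
            expected = np.array([p, 1 - p]) * len(group)
            if expected.min() == 0:
                assert hits == len(group) * p
                continue
            chi2 = stats.chisquare([hits, len(group) - hits], expected)
            assert chi2.pvalue > 0.01, (fid, label, hits / len(group), p)


def test_all_five_patterns_exercised_under_defaults():
    from hepanlp.fenlp import build_feature_set

    corpus = generate_corpus(GeneratorConfig(seed=3))
    feats = features_for_corpus(corpus, default_lexicon())
    retained = build_feature_set(feats)
    patterns = set()
    by_key = {}
    for fs in feats.values():
        for f in fs:
            by_key[f.key] = f.pattern
    for key, _ in retained:
        patterns.add(by_key[key])
    assert patterns == {
        "Location+Density",
        "Location+Enhancement",
        "Location+Enhancement+Modifier",
        "Location+Density+Modifier",
        "Location+Morphology",
    }
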