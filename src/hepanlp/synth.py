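"""Seeded generator of synthetic Chinese CT radiology reports.

The generator emulates the corpus this pipeline targets: 480 liver-cancer
and 609 non-cancer findings texts in which arterial-phase
hyperenhancement (APHE) appears in 442 cancer and 160 non-cancer reports
(602 overall) and portal/delayed washout (PDPH) in 330, all of them
cancer.  Mentions vary between full phrases, the two-character
abbreviations 快进/快出, and CT-value style wordings, mirroring the
surface variety real radiologists produce.

Each report is 3–10 template sentences: an opening line, evidence
sentences carrying gold BIO tags, lexicon-built sentences realizing the
five rule-extraction patterns with class-conditional prevalences, and
hard-negative distractors (negated enhancement, enhancement words outside
the arterial/portal context) carrying all-O tags, so labeling the corpus
is not trivially perfect.  Sentence order is shuffled per report.

Identical seed and configuration yield a byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import LabeledReport, Lexicon
from .tagging import Span, spans_to_tags

# ---------------------------------------------------------------------------
# Phrase bank: evidence mentions with their tagged spans


def phrase_bank() -> list[tuple[str, str, tuple[int, int]]]:
    """Evidence phrase templates: (text, entity type, tagged span).

    Contains the five canonical full expressions, both abbreviations and
    one CT-value style mention per entity type; each span covers the full
    phrase.
    """
    full = [
        ("增强后动脉期明显不均匀强化", "APHE"),
        ("动脉期强化明显", "APHE"),
        ("动脉期可见多发强化灶", "APHE"),
        ("门脉期相对低密度", "PDPH"),
        ("门脉期可见消退", "PDPH"),
        ("快进", "APHE"),
        ("快出", "PDPH"),
        ("动脉期CT值约85HU明显升高", "APHE"),
        ("门脉期CT值降至45HU", "PDPH"),
    ]
    return [(text, ent, (0, len(text))) for text, ent in full]


_FULL_PHRASES = {
    "APHE": ["增强后动脉期明显不均匀强化", "动脉期强化明显", "动脉期可见多发强化灶"],
    "PDPH": ["门脉期相对低密度", "门脉期可见消退"],
}
_CT_VALUE_PHRASES = {
    "APHE": ["动脉期CT值约85HU明显升高"],
    "PDPH": ["门脉期CT值降至45HU"],
}
_ABBREV_SENTENCES = {
    # abbreviation embedded mid-sentence; only the two characters are tagged
    "APHE": [("增强呈快进表现", 3), ("病灶强化呈快进改变", 5)],
    "PDPH": [("增强呈快出表现", 3), ("病灶强化呈快出改变", 5)],
}
#: lesion-context prefixes for full/CT-value mentions (may themselves
#: contain lexicon terms, so evidence sentences also feed the rule pipeline)
_CONTEXT_PREFIXES = [
    "肝内见结节状异常密度灶，",
    "肝右叶见类圆形低密度灶，",
    "肝左叶见占位性病变，",
    "",
]

_OPENERS = [
    "肝脏大小形态未见明显异常",
    "扫描层面诸骨未见异常",
    "腹腔未见积液",
    "胆囊壁不厚",
]

#: hard negatives: enhancement vocabulary outside an evidence context,
#: negations, non-hepatic organs; all carry all-O gold tags
_DISTRACTORS = [
    "动脉期未见强化",
    "动脉期未见明显异常强化灶",
    "增强扫描未见强化",
    "门脉期密度均匀",
    "延迟期无明显强化",
    "平扫肝实质密度均匀",
    "脾脏大小形态未见异常",
    "双肾未见异常强化灶",
    "门脉期及延迟期未见异常",
    # near-miss negatives sharing long prefixes with true evidence phrases
    "动脉期强化不明显",
    "门脉期呈相对等密度",
]

#: feature-sentence templates realizing the five extraction patterns;
#: several have surface variants (including synonym variants of 肝脏)
_FEATURE_SENTENCES: dict[str, list[str]] = {
    "liver_low_density": ["肝脏内见低密度影", "肝内见低密度影"],
    "liver_no_enhance": ["肝脏增强扫描未见强化"],
    "rlobe_ring_enh_mod": ["肝右叶环形强化明显"],
    "llobe_low_density_mod": ["肝左叶低密度影边界不清"],
    "liver_morph": ["肝脏形态失常，肝裂增宽"],
    "spleen_morph": ["脾脏体积增大"],
}

#: class-conditional prevalences (P(feature | cancer), P(feature | benign))
DEFAULT_FEATURE_PREVALENCES: dict[str, tuple[float, float]] = {
    "liver_low_density": (0.70, 0.30),
    "liver_no_enhance": (0.25, 0.45),
    "rlobe_ring_enh_mod": (0.45, 0.15),
    "llobe_low_density_mod": (0.35, 0.20),
    "liver_morph": (0.55, 0.15),
    "spleen_morph": (0.30, 0.35),
}


def default_lexicon() -> Lexicon:
    """~60-term lexicon across the five entity types, with synonyms.

    Curated so that the generator's feature sentences realize all five
    extraction patterns, including 肝脏+低密度影 and
    肝脏+增强扫描未见强化.
    """
    entries = {}
    for term in (
        "肝脏 肝左叶 肝右叶 肝尾叶 胆囊 脾脏 胰腺 肾脏 门静脉 肝门 "
        "腹膜后 腹腔 肠系膜 膀胱 前列腺 子宫 肾上腺 下腔静脉"
    ).split():
        entries[term] = "Location"
    for term in (
        "低密度影 高密度影 等密度影 混杂密度影 低密度灶 结节影 钙化灶 "
        "密度均匀 密度不均 囊性密度影"
    ).split():
        entries[term] = "Density"
    for term in (
        "强化 环形强化 明显强化 未见强化 增强扫描未见强化 不均匀强化 "
        "轻度强化 延迟强化"
    ).split():
        entries[term] = "Enhancement"
    for term in (
        "形态失常 肝裂增宽 体积增大 体积缩小 边缘光整 轮廓不规则 "
        "结节状改变 占位性病变 形态饱满"
    ).split():
        entries[term] = "Morphology"
    for term in "明显 边界不清 边界清楚 边缘清楚 欠均匀 较前相仿 稍大 轻度".split():
        entries[term] = "Modifier"
    synonyms = {"肝": "肝脏", "肝实质": "肝脏", "双肾": "肾脏", "脾": "脾脏"}
    return Lexicon(entries=entries, synonyms=synonyms)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class GeneratorConfig:
    """Corpus-level knobs; defaults are the emulated study conditions."""

    seed: int = 0
    n_cancer: int = 480
    n_noncancer: int = 609
    p_aphe_given_cancer: float = 442 / 480
    p_aphe_given_noncancer: float = 160 / 609
    p_pdph_given_cancer: float = 330 / 480
    p_pdph_given_noncancer: float = 0.0
    p_abbreviation: float = 0.3
    p_ct_value: float = 0.15
    distractor_rate: float = 0.3
    feature_prevalences: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_PREVALENCES)
    )

    def validate(self) -> None:
        if self.n_cancer < 0 or self.n_noncancer < 0:
            raise ValueError("report counts must be non-negative")
        probs = [
            self.p_aphe_given_cancer,
            self.p_aphe_given_noncancer,
            self.p_pdph_given_cancer,
            self.p_pdph_given_noncancer,
            self.p_abbreviation,
            self.p_ct_value,
            self.distractor_rate,
        ] + [p for pair in self.feature_prevalences.values() for p in pair]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for fid in self.feature_prevalences:
            if fid not in _FEATURE_SENTENCES:
                raise ValueError(f"unknown feature sentence id {fid!r}")


# ---------------------------------------------------------------------------
# Report assembly


def _evidence_sentence(
    entity: str, rng: np.random.Generator, cfg: GeneratorConfig
) -> tuple[str, list[tuple[str, int, int]]]:
    """One sentence carrying a tagged mention of ``entity``."""
    u = rng.random()
    if u < cfg.p_abbreviation:
        sent, off = _ABBREV_SENTENCES[entity][rng.integers(2)]
        return sent, [(entity, off, off + 2)]
    if u < cfg.p_abbreviation + cfg.p_ct_value:
        phrase = _CT_VALUE_PHRASES[entity][0]
    else:
        choices = _FULL_PHRASES[entity]
        phrase = choices[rng.integers(len(choices))]
    prefix = _CONTEXT_PREFIXES[rng.integers(len(_CONTEXT_PREFIXES))]
    return prefix + phrase, [(entity, len(prefix), len(prefix) + len(phrase))]


def _build_report(
    report_id: str, diagnosis: int, rng: np.random.Generator, cfg: GeneratorConfig
) -> LabeledReport:
    has_aphe = rng.random() < (
        cfg.p_aphe_given_cancer if diagnosis else cfg.p_aphe_given_noncancer
    )
    has_pdph = rng.random() < (
        cfg.p_pdph_given_cancer if diagnosis else cfg.p_pdph_given_noncancer
    )

    sentences: list[tuple[str, list[tuple[str, int, int]]]] = []
    if has_aphe:
        sentences.append(_evidence_sentence("APHE", rng, cfg))
    if has_pdph:
        sentences.append(_evidence_sentence("PDPH", rng, cfg))
    for fid in sorted(cfg.feature_prevalences):
        p1, p0 = cfg.feature_prevalences[fid]
        if rng.random() < (p1 if diagnosis else p0):
            variants = _FEATURE_SENTENCES[fid]
            sentences.append((variants[rng.integers(len(variants))], []))
    n_distract = int(rng.binomial(2, cfg.distractor_rate))
    picks = rng.choice(len(_DISTRACTORS), size=n_distract, replace=False)
    for i in picks:
        sentences.append((_DISTRACTORS[i], []))
    if len(sentences) < 10:
        sentences.append((_OPENERS[rng.integers(len(_OPENERS))], []))
    while len(sentences) < 3:
        sentences.append((_DISTRACTORS[rng.integers(len(_DISTRACTORS))], []))

    order = rng.permutation(len(sentences))
    text_parts: list[str] = []
    spans: list[Span] = []
    offset = 0
    for i in order:
        sent, sent_spans = sentences[i]
        full = sent + "。"
        for ent, s, e in sent_spans:
            spans.append(Span(ent, offset + s, offset + e, full[s:e]))
        text_parts.append(full)
        offset += len(full)
    text = "".join(text_parts)
    tags = spans_to_tags(len(text), spans)
    return LabeledReport(
        report_id=report_id,
        text=text,
        gold_tags=tags,
        diagnosis=diagnosis,
        evidence_flags=(int(has_aphe), int(has_pdph)),
    )


def generate_corpus(
    config: GeneratorConfig | None = None, lexicon: Lexicon | None = None
) -> list[LabeledReport]:
    """Generate the full synthetic corpus (cancer reports first by id).

    ``lexicon`` defaults to :func:`default_lexicon`; the generator's
    feature sentences are phrased in its terms, and a replacement lexicon
    must still cover them for the extraction patterns to fire.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    lex = lexicon or default_lexicon()
    if len(lex) == 0:
        raise ValueError("lexicon must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    reports = []
    n_total = cfg.n_cancer + cfg.n_noncancer
    width = max(4, len(str(n_total)))
    for i in range(n_total):
        diagnosis = 1 if i < cfg.n_cancer else 0
        reports.append(
            _build_report(f"synth-{i:0{width}d}", diagnosis, rng, cfg)
        )
    return reports


#: expected retained-feature keys for the planted sentences (used by the
#: documentation and tests; derived from the templates above)
PLANTED_FEATURE_KEYS: dict[str, tuple[str, ...]] = {
    "liver_low_density": ("肝脏+低密度影",),
    "liver_no_enhance": ("肝脏+增强扫描未见强化",),
    "rlobe_ring_enh_mod": ("肝右叶+环形强化+明显",),
    "llobe_low_density_mod": ("肝左叶+低密度影+边界不清",),
    "liver_morph": ("肝脏+形态失常", "肝脏+肝裂增宽"),
    "spleen_morph": ("脾脏+体积增大",),
}
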