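"""Rule-based radiological feature extraction (four-stage pipeline).

The pipeline turns free-text findings into discrete radiological features
in four successive steps driven entirely by a curated lexicon:

1. word segmentation — forward maximum matching against lexicon terms;
2. entity annotation — five entity types: Location, Morphology, Density,
   Enhancement, Modifier;
3. synonym canonicalization — variants replaced by their canonical term;
4. relationship extraction — entity-type patterns assemble features such
   as 肝脏+低密度影 (liver + low density).

Five patterns are recognized: Location+Density, Location+Enhancement,
Location+Enhancement+Modifier, Location+Density+Modifier, and
Location+Morphology.  Attributes attach to the nearest preceding Location
within a sentence; a Modifier immediately following an attached Density or
Enhancement upgrades the feature to the three-term pattern.  Features are
counted once per report, and only those occurring in at least
``min_count`` reports (default 3, i.e. "more than twice") are retained.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import LabeledReport, Lexicon

PATTERNS = (
    "Location+Density",
    "Location+Enhancement",
    "Location+Enhancement+Modifier",
    "Location+Density+Modifier",
    "Location+Morphology",
)

_ATTRIBUTE_TYPES = ("Density", "Enhancement", "Morphology")

#: Sentence terminators; clause commas do NOT split, because feature
#: descriptions routinely span multiple clauses.
_SENTENCE_SPLIT = re.compile(r"[。；！？;\n]")


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    entity_type: str | None = None


@dataclass(frozen=True)
class RadFeature:
    """One entity-pattern instance, keyed by its joined canonical terms."""

    pattern: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if len(self.terms) != self.pattern.count("+") + 1:
            raise ValueError("term count does not match pattern arity")

    @property
    def key(self) -> str:
        return "+".join(self.terms)


def split_sentences(text: str) -> list[str]:
    """Split report text into sentences on 。；！？; and newline."""
    return [s for s in _SENTENCE_SPLIT.split(text) if s]


def segment(sentence: str, lexicon: Lexicon) -> list[Token]:
    """Forward maximum matching: longest lexicon term first.

    Characters not covered by any term become single-character untyped
    tokens; tokens tile the sentence without overlap.
    """
    sentence = unicodedata.normalize("NFC", sentence)
    terms = lexicon.terms()
    max_len = max((len(t) for t in terms), default=1)
    tokens: list[Token] = []
    i = 0
    while i < len(sentence):
        match = None
        for L in range(min(max_len, len(sentence) - i), 0, -1):
            cand = sentence[i : i + L]
            if cand in terms:
                match = cand
                break
        if match is None:
            tokens.append(Token(sentence[i], i, i + 1))
            i += 1
        else:
            etype = lexicon.lookup(match)[1]
            tokens.append(Token(match, i, i + len(match), etype))
            i += len(match)
    return tokens


def annotate_entities(tokens: Sequence[Token], lexicon: Lexicon) -> list[Token]:
    """Keep the tokens whose (canonicalized) surface is a lexicon entry."""
    out = []
    for tok in tokens:
        hit = lexicon.lookup(tok.surface)
        if hit is not None:
            out.append(Token(tok.surface, tok.start, tok.end, hit[1]))
    return out


def canonicalize(entities: Sequence[Token], lexicon: Lexicon) -> list[Token]:
    """Replace every surface by its canonical term; idempotent."""
    out = []
    for tok in entities:
        canon = lexicon.canonical(tok.surface)
        if canon not in lexicon.entries:
            raise ValueError(f"{tok.surface!r} does not resolve to a lexicon entry")
        out.append(Token(canon, tok.start, tok.end, lexicon.entries[canon]))
    return out


def extract_features(entities: Sequence[Token]) -> list[RadFeature]:
    """Assemble pattern features from one sentence's canonical entities.

    Attributes occurring after a Location and before the next Location
    attach to it; a Modifier immediately following an attached attribute
    upgrades that feature to the matching three-term pattern (Morphology
    has no modified pattern).  Duplicates within the sentence collapse.
    """
    features: list[RadFeature] = []
    location: Token | None = None
    last_attr: RadFeature | None = None  # most recent 2-term feature
    for tok in entities:
        if tok.entity_type == "Location":
            location = tok
            last_attr = None
        elif tok.entity_type in _ATTRIBUTE_TYPES:
            if location is not None:
                feat = RadFeature(
                    f"Location+{tok.entity_type}", (location.surface, tok.surface)
                )
                features.append(feat)
                last_attr = feat if tok.entity_type != "Morphology" else None
            else:
                last_attr = None
        elif tok.entity_type == "Modifier":
            if last_attr is not None:
                features[-1] = RadFeature(
                    last_attr.pattern + "+Modifier", last_attr.terms + (tok.surface,)
                )
            last_attr = None
    seen: set[str] = set()
    unique = []
    for f in features:
        if f.key not in seen:
            seen.add(f.key)
            unique.append(f)
    return unique


def features_for_text(text: str, lexicon: Lexicon) -> list[RadFeature]:
    """Run all four stages over every sentence of one report."""
    out: list[RadFeature] = []
    seen: set[str] = set()
    for sentence in split_sentences(text):
        tokens = segment(sentence, lexicon)
        entities = annotate_entities(tokens, lexicon)
        entities = canonicalize(entities, lexicon)
        for feat in extract_features(entities):
            if feat.key not in seen:
                seen.add(feat.key)
                out.append(feat)
    return out


def features_for_corpus(
    reports: Sequence[LabeledReport], lexicon: Lexicon
) -> dict[str, list[RadFeature]]:
    return {r.report_id: features_for_text(r.text, lexicon) for r in reports}


def build_feature_set(
    corpus_features: dict[str, list[RadFeature]] | Iterable[Iterable[RadFeature]],
    min_count: int = 3,
) -> list[tuple[str, int]]:
    """Retained feature vocabulary with report-level counts.

    A feature mentioned several times in one report counts once (the
    downstream vectors are 0-1 per report).  Features kept iff their
    count ≥ ``min_count``; sorted by descending count, then key.
    """
    if isinstance(corpus_features, dict):
        per_report = corpus_features.values()
    else:
        per_report = corpus_features
    counts: Counter[str] = Counter()
    for feats in per_report:
        counts.update({f.key for f in feats})
    retained = [(k, c) for k, c in counts.items() if c >= min_count]
    retained.sort(key=lambda kc: (-kc[1], kc[0]))
    return retained
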