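"""Character-level BIO tag scheme for APHE/PDPH phrase recognition.

Radiology findings are labelled per Unicode character (digits, Latin
letters and punctuation inside CT-value expressions included) with one of
five tags: ``B-APHE``, ``I-APHE``, ``B-PDPH``, ``I-PDPH``, ``O``.  APHE is
arterial-phase hyperenhancement, PDPH portal/delayed-phase washout — the
two contrast-CT hallmarks of hepatocellular carcinoma.

All offsets are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

ENTITY_TYPES = ("APHE", "PDPH")

#: Closed tag set; index order fixes tie-breaking in Viterbi decoding.
TAGS = ("B-APHE", "I-APHE", "B-PDPH", "I-PDPH", "O")
TAG_TO_INDEX = {t: i for i, t in enumerate(TAGS)}
O_INDEX = TAG_TO_INDEX["O"]
N_TAGS = len(TAGS)


def tag_entity(tag: str) -> str | None:
    """Entity type carried by a tag, or None for ``O``."""
    if tag == "O":
        return None
    return tag.split("-", 1)[1]


@dataclass(frozen=True)
class Span:
    """A maximal B-X (I-X)* run in canonical form.

    ``start`` inclusive, ``end`` exclusive character offsets into the text
    the tags were aligned with; ``surface`` is ``text[start:end]``.
    """

    entity_type: str
    start: int
    end: int
    surface: str = ""

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.entity_type!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span offsets [{self.start}, {self.end})")


class IllegalTagSequenceError(ValueError):
    """Raised when a tag sequence violates BIO legality."""

    def __init__(self, position: int, message: str):
        self.position = position
        super().__init__(f"position {position}: {message}")


def _check_known(tags: Sequence[str]) -> None:
    for i, t in enumerate(tags):
        if t not in TAG_TO_INDEX:
            raise IllegalTagSequenceError(i, f"unknown tag label {t!r}")


def validate_tags(tags: Sequence[str]) -> list[int]:
    """Return every index whose tag violates BIO legality.

    An ``I-X`` may only follow ``B-X`` or ``I-X`` of the same entity type.
    The empty sequence is legal.  Unknown labels are rejected with their
    index via :class:`IllegalTagSequenceError`.
    """
    _check_known(tags)
    violations = []
    prev = "O"
    for i, t in enumerate(tags):
        if t.startswith("I-") and tag_entity(prev) != tag_entity(t):
            violations.append(i)
        prev = t
    return violations


def repair_orphan_i(tags: Sequence[str]) -> list[str]:
    """Coerce each orphan ``I-X`` (no same-type B/I predecessor) to ``B-X``.

    Models may emit illegal sequences; repairing instead of deleting
    preserves the predicted extent of the evidence phrase.
    """
    _check_known(tags)
    out: list[str] = []
    prev = "O"
    for t in tags:
        if t.startswith("I-") and tag_entity(prev) != tag_entity(t):
            t = "B-" + tag_entity(t)
        out.append(t)
        prev = t
    return out


def tags_to_spans(text: str, tags: Sequence[str]) -> list[Span]:
    """Extract one :class:`Span` per maximal ``B-X (I-X)*`` run.

    Requires a legal sequence aligned 1:1 with ``text``; spans come back
    non-overlapping and sorted by start offset.
    """
    if len(text) != len(tags):
        raise ValueError(f"text length {len(text)} != tags length {len(tags)}")
    bad = validate_tags(tags)
    if bad:
        raise IllegalTagSequenceError(bad[0], f"illegal tag {tags[bad[0]]!r}")
    spans: list[Span] = []
    start = None
    ent = None
    for i, t in enumerate(tags):
        if t.startswith("B-"):
            if start is not None:
                spans.append(Span(ent, start, i, text[start:i]))
            start, ent = i, tag_entity(t)
        elif t == "O":
            if start is not None:
                spans.append(Span(ent, start, i, text[start:i]))
            start, ent = None, None
        # I-X continues the open run (legality guarantees same type)
    if start is not None:
        spans.append(Span(ent, start, len(tags), text[start:]))
    return spans


def spans_to_tags(length: int, spans: Iterable[Span]) -> list[str]:
    """Inverse of :func:`tags_to_spans` on legal inputs.

    Spans must be non-overlapping and lie within ``[0, length)``.
    """
    tags = ["O"] * length
    for sp in spans:
        if sp.end > length:
            raise ValueError(f"span [{sp.start}, {sp.end}) exceeds length {length}")
        for i in range(sp.start, sp.end):
            if tags[i] != "O":
                raise ValueError(f"overlapping spans at position {i}")
            tags[i] = ("B-" if i == sp.start else "I-") + sp.entity_type
    return tags


def entity_runs(tags: Sequence[str]) -> list[tuple[str, int, int]]:
    """Maximal runs of consecutive characters carrying one entity type.

    Unlike :func:`tags_to_spans` this ignores the B/I distinction: two
    adjacent spans of the same type (``B-X`` followed by ``B-X``) merge
    into one run, because report-level criteria are phrased over
    continuous characters, not spans.  Returns (entity_type, start, end).
    """
    _check_known(tags)
    runs: list[tuple[str, int, int]] = []
    start = None
    ent = None
    for i, t in enumerate(tags):
        e = tag_entity(t)
        if e != ent:
            if ent is not None:
                runs.append((ent, start, i))
            start, ent = (i, e) if e is not None else (None, None)
    if ent is not None:
        runs.append((ent, start, len(tags)))
    return runs
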