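"""Report/annotation/lexicon containers and their on-disk formats.

Three plain-text formats are used throughout:

* CoNLL-style two-column character/tag files — one ``char<TAB>tag`` line
  per character, blank line between sequences;
* JSON-Lines report files — one JSON object per report with the
  :class:`LabeledReport` fields;
* TSV lexicon files — ``term<TAB>entity_type`` for canonical entries,
  ``variant<TAB>entity_type<TAB>canonical`` for synonyms.

All files are UTF-8 without BOM; text is NFC-normalized on read so that
substring matching of abbreviations such as 快进/快出 is stable.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .tagging import TAG_TO_INDEX, validate_tags

LEXICON_ENTITY_TYPES = ("Location", "Morphology", "Density", "Enhancement", "Modifier")


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass
class LabeledReport:
    """One radiology report (Findings-section text).

    ``gold_tags`` when present is aligned 1:1 with ``text``.  ``diagnosis``
    is 1 for liver cancer.  ``evidence_flags`` is the report-level
    (APHE, PDPH) pair; the two are not mutually exclusive — a report can
    carry both.
    """

    report_id: str
    text: str
    gold_tags: list[str] | None = None
    diagnosis: int | None = None
    evidence_flags: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.text = _nfc(self.text)
        if self.gold_tags is not None and len(self.gold_tags) != len(self.text):
            raise ValueError(
                f"report {self.report_id}: {len(self.gold_tags)} tags "
                f"for {len(self.text)} characters"
            )
        if self.diagnosis is not None and self.diagnosis not in (0, 1):
            raise ValueError(f"report {self.report_id}: diagnosis must be 0/1")
        if self.evidence_flags is not None:
            self.evidence_flags = tuple(self.evidence_flags)  # type: ignore[assignment]
            if len(self.evidence_flags) != 2 or any(
                f not in (0, 1) for f in self.evidence_flags
            ):
                raise ValueError(f"report {self.report_id}: bad evidence flags")


@dataclass
class Lexicon:
    """Term → entity-type map plus synonym → canonical map.

    Invariants: every synonym's canonical term is itself an entry; no term
    maps to two entity types.
    """

    entries: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, etype in self.entries.items():
            if etype not in LEXICON_ENTITY_TYPES:
                raise ValueError(f"term {term!r}: unknown entity type {etype!r}")
        for variant, canonical in self.synonyms.items():
            if canonical not in self.entries:
                raise ValueError(
                    f"synonym {variant!r} points to unknown canonical {canonical!r}"
                )
            if variant in self.entries and self.entries[variant] != self.entries[canonical]:
                raise ValueError(f"term {variant!r} maps to two entity types")

    def terms(self) -> set[str]:
        """All matchable surfaces: canonical entries and synonym variants."""
        return set(self.entries) | set(self.synonyms)

    def canonical(self, term: str) -> str:
        """Canonical form of a surface (identity for canonical entries)."""
        return self.synonyms.get(term, term)

    def lookup(self, term: str) -> tuple[str, str] | None:
        """(canonical term, entity type) for a surface, or None."""
        canon = self.canonical(term)
        etype = self.entries.get(canon)
        return None if etype is None else (canon, etype)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# CoNLL two-column character/tag files


def read_conll(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read a two-column character/tag file into (text, tags) pairs."""
    sequences: list[tuple[str, list[str]]] = []
    chars: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                if chars:
                    sequences.append(("".join(chars), tags))
                    chars, tags = [], []
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            ch, tag = _nfc(parts[0]), parts[1]
            if len(ch) != 1:
                raise ValueError(f"{path}:{lineno}: first column must be one character")
            if tag not in TAG_TO_INDEX:
                raise ValueError(f"{path}:{lineno}: unknown tag {tag!r}")
            chars.append(ch)
            tags.append(tag)
    if chars:
        sequences.append(("".join(chars), tags))
    for i, (text, tg) in enumerate(sequences):
        bad = validate_tags(tg)
        if bad:
            raise ValueError(f"{path}: sequence {i}: illegal tag at position {bad[0]}")
    return sequences


def write_conll(path: str | Path, sequences: Iterable[tuple[str, Sequence[str]]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for text, tags in sequences:
            if len(text) != len(tags):
                raise ValueError("text/tags length mismatch")
            for ch, tag in zip(text, tags):
                fh.write(f"{ch}\t{tag}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# JSON-Lines report files


def read_reports_jsonl(path: str | Path) -> list[LabeledReport]:
    """Read one report object per line; missing optional fields stay absent."""
    reports: list[LabeledReport] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                flags = obj.get("evidence_flags")
                reports.append(
                    LabeledReport(
                        report_id=str(obj["report_id"]),
                        text=obj["text"],
                        gold_tags=obj.get("gold_tags"),
                        diagnosis=obj.get("diagnosis"),
                        evidence_flags=tuple(flags) if flags is not None else None,
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed report line: {exc}") from exc
    return reports


def write_reports_jsonl(path: str | Path, reports: Iterable[LabeledReport]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            obj: dict = {"report_id": r.report_id, "text": r.text}
            if r.gold_tags is not None:
                obj["gold_tags"] = r.gold_tags
            if r.diagnosis is not None:
                obj["diagnosis"] = r.diagnosis
            if r.evidence_flags is not None:
                obj["evidence_flags"] = list(r.evidence_flags)
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# TSV lexicon files


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a TSV lexicon (term, entity type, optional canonical term)."""
    entries: dict[str, str] = {}
    synonyms: dict[str, str] = {}
    rows: list[tuple[int, str, str, str | None]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = [_nfc(p) for p in line.split("\t")]
            if len(parts) == 2:
                rows.append((lineno, parts[0], parts[1], None))
            elif len(parts) == 3:
                rows.append((lineno, parts[0], parts[1], parts[2]))
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
    # canonical entries first so synonym targets resolve regardless of order
    for lineno, term, etype, canonical in rows:
        if canonical is None:
            if etype not in LEXICON_ENTITY_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown entity type {etype!r}")
            if term in entries and entries[term] != etype:
                raise ValueError(f"{path}:{lineno}: term {term!r} has conflicting types")
            entries[term] = etype
    for lineno, term, etype, canonical in rows:
        if canonical is not None:
            if canonical not in entries:
                raise ValueError(
                    f"{path}:{lineno}: synonym {term!r} points to unknown "
                    f"canonical {canonical!r}"
                )
            if entries[canonical] != etype:
                raise ValueError(
                    f"{path}:{lineno}: synonym {term!r} type {etype!r} conflicts "
                    f"with canonical {canonical!r} type {entries[canonical]!r}"
                )
            synonyms[term] = canonical
    return Lexicon(entries=entries, synonyms=synonyms)


def write_lexicon(path: str | Path, lexicon: Lexicon) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(lexicon.entries):
            fh.write(f"{term}\t{lexicon.entries[term]}\n")
        for variant in sorted(lexicon.synonyms):
            canonical = lexicon.synonyms[variant]
            fh.write(f"{variant}\t{lexicon.entries[canonical]}\t{canonical}\n")
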