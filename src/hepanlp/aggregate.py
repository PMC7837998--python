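"""Report-level APHE/PDPH presence from character-level predictions.

Two ordered criteria decide, per entity type independently, whether a
report carries the evidence:

1. the two-character abbreviation (快进 for APHE, 快出 for PDPH) occurs
   literally anywhere in the text — checked first, on the characters only;
2. otherwise, some maximal run of consecutive characters predicted as that
   entity type is longer than 3 characters (run length ≥ 4 by default).

Single-character predictions are treated as noise and never set a flag.
The two flags are not mutually exclusive.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Sequence

from .corpus import LabeledReport
from .tagging import entity_runs

ABBREVIATIONS = {"APHE": "快进", "PDPH": "快出"}

#: "More than 3 continuous characters" read as run length ≥ 4.
DEFAULT_MIN_RUN = 4


@dataclass(frozen=True)
class FlagProvenance:
    """Which criterion fired and the triggering substring/run offsets."""

    criterion: int  # 1 = abbreviation substring, 2 = predicted run
    start: int
    end: int
    surface: str


@dataclass
class EvidenceFlags:
    aphe: int
    pdph: int
    aphe_provenance: FlagProvenance | None = None
    pdph_provenance: FlagProvenance | None = None

    def __post_init__(self) -> None:
        if (self.aphe == 1) != (self.aphe_provenance is not None) or (
            self.pdph == 1
        ) != (self.pdph_provenance is not None):
            raise ValueError("provenance must be present iff the flag is set")

    def as_tuple(self) -> tuple[int, int]:
        return (self.aphe, self.pdph)


def _detect_one(
    text: str, tags: Sequence[str] | None, entity: str, min_run: int
) -> FlagProvenance | None:
    abbrev = ABBREVIATIONS[entity]
    pos = text.find(abbrev)
    if pos >= 0:
        return FlagProvenance(1, pos, pos + len(abbrev), abbrev)
    if tags is None:
        return None
    for ent, start, end in entity_runs(tags):
        if ent == entity and end - start >= min_run:
            return FlagProvenance(2, start, end, text[start:end])
    return None


def detect_report_level(
    text: str,
    predicted_tags: Sequence[str] | None = None,
    min_run: int = DEFAULT_MIN_RUN,
) -> EvidenceFlags:
    """Apply the two ordered criteria to one report.

    ``predicted_tags`` may be absent, in which case only the abbreviation
    criterion applies.  Runs are counted over entity type (B and I alike),
    so two adjacent same-type spans merge; a run breaks on any change of
    entity type.
    """
    text = unicodedata.normalize("NFC", text)
    if predicted_tags is not None and len(predicted_tags) != len(text):
        raise ValueError(
            f"{len(predicted_tags)} tags for {len(text)} characters"
        )
    aphe = _detect_one(text, predicted_tags, "APHE", min_run)
    pdph = _detect_one(text, predicted_tags, "PDPH", min_run)
    return EvidenceFlags(
        aphe=int(aphe is not None),
        pdph=int(pdph is not None),
        aphe_provenance=aphe,
        pdph_provenance=pdph,
    )


def flags_for_corpus(
    reports: Sequence[LabeledReport],
    model=None,
    predicted_tags: Sequence[Sequence[str]] | None = None,
    min_run: int = DEFAULT_MIN_RUN,
) -> dict[str, EvidenceFlags]:
    """Predict tags (or use supplied ones) and aggregate every report.

    ``model`` is any object with ``predict_tags(text)``; pass
    ``predicted_tags`` instead to reuse precomputed predictions.
    """
    if predicted_tags is None:
        if model is None:
            predicted_tags = [None] * len(reports)
        else:
            predicted_tags = [model.predict_tags(r.text) for r in reports]
    out: dict[str, EvidenceFlags] = {}
    for report, tags in zip(reports, predicted_tags):
        out[report.report_id] = detect_report_level(report.text, tags, min_run)
    return out
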