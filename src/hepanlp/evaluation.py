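"""Corpus split and labeler scoring at character and report level.

Character-level scoring is per-entity binary by default: a character is a
positive for APHE if its tag carries the APHE entity (B and I alike), and
likewise for PDPH; precision/recall/F1 are micro-averaged over all
characters of the corpus.  This entity-membership definition is one of
two defensible readings of per-entity rows in a character-level score
table; a strict mode that requires the exact BIO label for a true
positive is available via ``mode="strict"``.

All metrics are reported in percent.  Zero-denominator conventions:
precision, recall and F1 are 0 when undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import LabeledReport
from .tagging import ENTITY_TYPES, tag_entity


@dataclass
class EntityMetrics:
    """Confusion counts and derived percentage metrics for one entity."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return 100.0 * (self.tp + self.tn) / total if total else 0.0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


@dataclass
class MetricsReport:
    """Per-entity metrics at one level (character or report)."""

    level: str
    per_entity: dict[str, EntityMetrics] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {e: m.as_dict() for e, m in self.per_entity.items()}


def split_corpus(
    reports: Sequence[LabeledReport], ratio: float = 0.8, seed: int = 0
) -> tuple[list[LabeledReport], list[LabeledReport]]:
    """Deterministic train/test partition, stratified by diagnosis.

    The training set holds ``ceil(ratio * n)`` reports overall, allocated
    across diagnosis strata by largest remainder so the split stays
    stratified at any corpus size.  Reports without a diagnosis form their
    own stratum.
    """
    if not reports:
        raise ValueError("empty corpus")
    n = len(reports)
    n_train = int(np.ceil(ratio * n))
    rng = np.random.default_rng(seed)
    strata: dict[object, list[int]] = {}
    for i, r in enumerate(reports):
        strata.setdefault(r.diagnosis, []).append(i)
    keys = sorted(strata, key=lambda k: (k is None, k))
    quotas = {k: ratio * len(strata[k]) for k in keys}
    take = {k: int(np.floor(quotas[k])) for k in keys}
    short = n_train - sum(take.values())
    # distribute the remainder to the largest fractional parts
    order = sorted(keys, key=lambda k: (-(quotas[k] - take[k]), -len(strata[k])))
    for k in order[: max(short, 0)]:
        take[k] += 1
    train_idx: list[int] = []
    test_idx: list[int] = []
    for k in keys:
        idx = np.array(strata[k])
        rng.shuffle(idx)
        train_idx.extend(idx[: take[k]])
        test_idx.extend(idx[take[k] :])
    train_idx.sort()
    test_idx.sort()
    return [reports[i] for i in train_idx], [reports[i] for i in test_idx]


def _binary_counts(gold: np.ndarray, pred: np.ndarray) -> EntityMetrics:
    tp = int(np.sum(gold & pred))
    fp = int(np.sum(~gold & pred))
    fn = int(np.sum(gold & ~pred))
    tn = int(np.sum(~gold & ~pred))
    return EntityMetrics(tp, fp, fn, tn)


def char_metrics(
    gold_sequences: Sequence[Sequence[str]],
    pred_sequences: Sequence[Sequence[str]],
    mode: str = "entity",
) -> MetricsReport:
    """Character-level metrics micro-pooled over the corpus.

    ``mode="entity"`` (default): a character counts as a positive for an
    entity if its tag carries that entity, regardless of B/I — a B-APHE
    predicted where gold is I-APHE is a true positive for APHE.
    ``mode="strict"``: the exact BIO label must match for a true positive
    (gold/pred positivity is still entity membership).
    """
    if len(gold_sequences) != len(pred_sequences):
        raise ValueError("gold and predicted corpora differ in size")
    golds: list[str] = []
    preds: list[str] = []
    for i, (g, p) in enumerate(zip(gold_sequences, pred_sequences)):
        if len(g) != len(p):
            raise ValueError(f"sequence {i}: gold length {len(g)} != predicted {len(p)}")
        golds.extend(g)
        preds.extend(p)
    report = MetricsReport(level="character")
    for entity in ENTITY_TYPES:
        g_ent = np.array([tag_entity(t) == entity for t in golds])
        p_ent = np.array([tag_entity(t) == entity for t in preds])
        if mode == "entity":
            m = _binary_counts(g_ent, p_ent)
        elif mode == "strict":
            exact = np.array([g == p for g, p in zip(golds, preds)])
            tp = int(np.sum(g_ent & p_ent & exact))
            fp = int(np.sum(p_ent)) - tp
            fn = int(np.sum(g_ent)) - tp
            tn = len(golds) - tp - fp - fn
            m = EntityMetrics(tp, fp, fn, tn)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        report.per_entity[entity] = m
    return report


def report_metrics(
    gold_flags: Mapping[str, tuple[int, int]],
    pred_flags: Mapping[str, tuple[int, int]],
) -> MetricsReport:
    """Report-level binary metrics per entity over aligned flag tables."""
    if not gold_flags:
        raise ValueError("empty corpus")
    if set(gold_flags) != set(pred_flags):
        missing = set(gold_flags) ^ set(pred_flags)
        raise ValueError(f"report id mismatch: {sorted(missing)[:5]}")
    ids = sorted(gold_flags)

    def pair(flags) -> tuple[int, int]:
        return flags.as_tuple() if hasattr(flags, "as_tuple") else tuple(flags)

    report = MetricsReport(level="report")
    for j, entity in enumerate(ENTITY_TYPES):
        g = np.array([pair(gold_flags[i])[j] == 1 for i in ids])
        p = np.array([pair(pred_flags[i])[j] == 1 for i in ids])
        report.per_entity[entity] = _binary_counts(g, p)
    return report
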