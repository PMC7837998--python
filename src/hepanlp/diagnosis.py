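"""Liver-cancer diagnosis from 0-1 evidence vectors.

Each report becomes a binary vector: APHE and PDPH presence flags first
(from the report-level aggregator), then one column per retained
rule-extracted radiological feature.  A random forest (bootstrap
aggregated CART trees, Gini splits) classifies cancer vs non-cancer, and
its mean-impurity-decrease importances rank the features; ranking is
restricted to features seen in more than ``min_frequency - 1`` reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .corpus import LabeledReport
from .fenlp import RadFeature

EVIDENCE_COLUMNS = ("APHE", "PDPH")


@dataclass
class FeatureMatrix:
    """0-1 design matrix with fixed, serialized column order."""

    feature_names: list[str]
    X: np.ndarray  # (n_reports, n_features) of {0, 1}
    report_ids: list[str]
    labels: np.ndarray | None = None  # aligned diagnosis, when known

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("feature matrix entries must be 0/1")
        if self.X.shape != (len(self.report_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match names/ids")

    def subset_rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        index = {rid: i for i, rid in enumerate(self.report_ids)}
        rows = [index[r] for r in ids]
        return FeatureMatrix(
            feature_names=self.feature_names,
            X=self.X[rows],
            report_ids=list(ids),
            labels=None if self.labels is None else self.labels[rows],
        )

    def subset_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        cols = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            feature_names=list(names),
            X=self.X[:, cols],
            report_ids=self.report_ids,
            labels=self.labels,
        )


def vectorize(
    reports: Sequence[LabeledReport],
    evidence_flags: Mapping[str, object],
    report_features: Mapping[str, Sequence[RadFeature]],
    retained: Sequence[str] | Sequence[tuple[str, int]],
) -> FeatureMatrix:
    """Assemble the 0-1 matrix: APHE, PDPH, then retained feature columns.

    ``evidence_flags`` maps report id → (aphe, pdph) (or EvidenceFlags);
    ``retained`` is the feature vocabulary (keys, optionally with counts).
    Raises if a report has no flags entry.
    """
    keys = [k if isinstance(k, str) else k[0] for k in retained]
    names = list(EVIDENCE_COLUMNS) + keys
    key_col = {k: j + 2 for j, k in enumerate(keys)}
    X = np.zeros((len(reports), len(names)), dtype=np.int8)
    labels = []
    for i, r in enumerate(reports):
        if r.report_id not in evidence_flags:
            raise KeyError(f"report {r.report_id} has no evidence flags")
        flags = evidence_flags[r.report_id]
        pair = flags.as_tuple() if hasattr(flags, "as_tuple") else tuple(flags)
        X[i, 0], X[i, 1] = pair
        for feat in report_features.get(r.report_id, ()):
            j = key_col.get(feat.key)
            if j is not None:
                X[i, j] = 1
        labels.append(r.diagnosis)
    y = None if any(l is None for l in labels) else np.array(labels, dtype=np.int8)
    return FeatureMatrix(names, X, [r.report_id for r in reports], y)


def fit_rf(
    matrix: FeatureMatrix,
    labels: np.ndarray | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the forest: ``n_trees`` trees, √p features per split, unlimited
    depth, deterministic given ``seed``."""
    y = matrix.labels if labels is None else np.asarray(labels)
    if y is None:
        raise ValueError("labels are required")
    if len(y) < 2 or len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    clf.fit(matrix.X, y)
    return clf


def evaluate_rf(
    clf: RandomForestClassifier, matrix: FeatureMatrix, labels: np.ndarray | None = None
) -> dict[str, float]:
    """Accuracy/precision/recall/F1 in percent; positive class = cancer."""
    y = matrix.labels if labels is None else np.asarray(labels)
    if y is None or len(y) == 0:
        raise ValueError("empty evaluation set")
    pred = clf.predict(matrix.X)
    tp = int(np.sum((y == 1) & (pred == 1)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": 100.0 * (tp + tn) / len(y),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


@dataclass
class ImportanceRanking:
    """Normalized Gini importances plus the frequency-filtered top list."""

    scores: dict[str, float]
    eligible: dict[str, bool]
    top: list[tuple[int, str, float, int]] = field(default_factory=list)


def rank_features(
    clf: RandomForestClassifier,
    feature_names: Sequence[str],
    frequencies: Mapping[str, int],
    min_frequency: int = 11,
    top_k: int = 10,
) -> ImportanceRanking:
    """Importance ranking restricted to features with corpus frequency
    ≥ ``min_frequency`` (i.e. "higher than 10" under the default).

    Sorted by importance descending, ties broken lexicographically.
    """
    importances = np.asarray(clf.feature_importances_, dtype=float)
    scores = {n: float(s) for n, s in zip(feature_names, importances)}
    eligible = {
        n: int(frequencies.get(n, 0)) >= min_frequency for n in feature_names
    }
    ranked = sorted(
        (n for n in feature_names if eligible[n]),
        key=lambda n: (-scores[n], n),
    )
    top = [
        (rank + 1, n, scores[n], int(frequencies.get(n, 0)))
        for rank, n in enumerate(ranked[:top_k])
    ]
    return ImportanceRanking(scores=scores, eligible=eligible, top=top)


class DiagnosisModel:
    """Thin estimator facade: fit on a FeatureMatrix, evaluate, rank."""

    def __init__(self, n_trees: int = 500, seed: int = 0):
        self.n_trees = n_trees
        self.seed = seed
        self.clf: RandomForestClassifier | None = None
        self.feature_names: list[str] = []

    def fit(self, matrix: FeatureMatrix) -> "DiagnosisModel":
        self.clf = fit_rf(matrix, n_trees=self.n_trees, seed=self.seed)
        self.feature_names = list(matrix.feature_names)
        return self

    def evaluate(self, matrix: FeatureMatrix) -> dict[str, float]:
        return evaluate_rf(self.clf, matrix)

    def rank(
        self, frequencies: Mapping[str, int], min_frequency: int = 11, top_k: int = 10
    ) -> ImportanceRanking:
        return rank_features(
            self.clf, self.feature_names, frequencies, min_frequency, top_k
        )


def planted_signal_recovery(
    n_seeds: int = 20,
    n_reports: int = 400,
    n_noise: int = 10,
    p_signal: tuple[float, float] = (0.8, 0.1),
    p_noise: float = 0.3,
    n_trees: int = 500,
    base_seed: int = 0,
) -> float:
    """Fraction of seeds in which a single strongly associated feature
    ranks first by importance among independent noise features.

    One feature has class-conditional presence ``p_signal`` (cancer,
    benign); the ``n_noise`` others are independent of the label.
    """
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        y = rng.integers(0, 2, n_reports)
        X = np.zeros((n_reports, 1 + n_noise), dtype=np.int8)
        X[:, 0] = rng.random(n_reports) < np.where(y == 1, *p_signal)
        X[:, 1:] = rng.random((n_reports, n_noise)) < p_noise
        names = ["signal"] + [f"noise{j}" for j in range(n_noise)]
        matrix = FeatureMatrix(names, X, [str(i) for i in range(n_reports)], y)
        clf = fit_rf(matrix, n_trees=n_trees, seed=base_seed + s)
        if int(np.argmax(clf.feature_importances_)) == 0:
            hits += 1
    return hits / n_seeds
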