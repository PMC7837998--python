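"""End-to-end orchestration: generate → split → label → aggregate →
rule features → diagnose, with every stage's output written to an
artifact directory and every random draw flowing from one pipeline seed.

Per-stage seeds derive from the pipeline seed by fixed offsets, so a
stage can be rerun in isolation and reproduce its output exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import aggregate, diagnosis, evaluation, fenlp, synth
from .corpus import LabeledReport, write_lexicon, write_reports_jsonl
from .crf import CrfTagger
from .neural import BiLstmCrfTagger, NeuralConfig

_STAGE_OFFSETS = {"generate": 1, "split": 2, "crf": 3, "neural": 4, "diagnosis": 5}


def stage_seed(pipeline_seed: int, stage: str) -> int:
    """Fixed-offset derivation; stays below 2^31."""
    return (pipeline_seed * 1009 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "artifacts"
    generator: synth.GeneratorConfig | None = None
    neural: NeuralConfig | None = None
    crf_l2: float = 0.1
    crf_max_iterations: int = 200
    split_ratio: float = 0.8
    min_run: int = aggregate.DEFAULT_MIN_RUN
    min_count: int = 3
    min_frequency: int = 11
    n_trees: int = 500
    top_k: int = 10

    def resolved(self) -> "PipelineConfig":
        gen = self.generator or synth.GeneratorConfig(seed=stage_seed(self.seed, "generate"))
        neural = self.neural or NeuralConfig(seed=stage_seed(self.seed, "neural"))
        return PipelineConfig(
            **{**asdict(self), "generator": gen, "neural": neural}  # type: ignore[arg-type]
        )


@dataclass
class PipelineResult:
    """Everything the downstream analysis needs, plus artifact paths."""

    config: PipelineConfig
    out_dir: Path
    corpus: list[LabeledReport]
    train_ids: list[str]
    test_ids: list[str]
    ner_metrics: dict
    diagnosis_metrics: dict
    ranking: diagnosis.ImportanceRanking
    retained: list[tuple[str, int]]
    epoch_losses: list[float] = field(default_factory=list)

    @property
    def metrics(self) -> dict:
        return {"ner": self.ner_metrics, "diagnosis": self.diagnosis_metrics}


def _fingerprint(data: str) -> str:
    return hashlib.sha256(data.encode("utf-8")).hexdigest()[:12]


def run_end_to_end(config: PipelineConfig | None = None, verbose: bool = False):
    cfg = (config or PipelineConfig()).resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str, t0: float) -> None:
        line = f"[{stage}] {msg} ({time.perf_counter() - t0:.1f}s)"
        log_lines.append(line)
        if verbose:
            print(line)

    # generate ---------------------------------------------------------
    t0 = time.perf_counter()
    lexicon = synth.default_lexicon()
    corpus = synth.generate_corpus(cfg.generator, lexicon)
    write_reports_jsonl(out / "reports.jsonl", corpus)
    write_lexicon(out / "lexicon.tsv", lexicon)
    log(
        "generate",
        f"{len(corpus)} reports, fingerprint "
        f"{_fingerprint(''.join(r.text for r in corpus))}",
        t0,
    )

    # split ------------------------------------------------------------
    t0 = time.perf_counter()
    train, test = evaluation.split_corpus(
        corpus, ratio=cfg.split_ratio, seed=stage_seed(cfg.seed, "split")
    )
    log("split", f"{len(train)} train / {len(test)} test", t0)
    train_pairs = [(r.text, r.gold_tags) for r in train]

    # labelers ---------------------------------------------------------
    t0 = time.perf_counter()
    crf = CrfTagger(l2_strength=cfg.crf_l2, max_iterations=cfg.crf_max_iterations)
    crf.fit(train_pairs)
    log("train-crf", f"{len(crf.feature_index)} features", t0)

    t0 = time.perf_counter()
    neural = BiLstmCrfTagger(cfg.neural).fit(train_pairs, verbose=verbose)
    log("train-neural", f"final loss {neural.epoch_losses_[-1]:.4f}", t0)

    # predict + aggregate + score -------------------------------------
    t0 = time.perf_counter()
    ner_metrics: dict = {}
    flags_by_model: dict[str, dict] = {}
    gold_flags = {r.report_id: r.evidence_flags for r in test}
    for name, model in (("crf", crf), ("neural", neural)):
        preds = model.predict_corpus([r.text for r in test])
        char = evaluation.char_metrics([r.gold_tags for r in test], preds)
        pred_flags = aggregate.flags_for_corpus(
            test, predicted_tags=preds, min_run=cfg.min_run
        )
        rep = evaluation.report_metrics(gold_flags, pred_flags)
        ner_metrics[name] = {"character": char.as_dict(), "report": rep.as_dict()}
        flags_by_model[name] = pred_flags
    log("evaluate-ner", "character + report metrics for crf, neural", t0)

    # flags for the whole corpus feed the diagnosis step (neural labeler,
    # mirroring the use of the best labeler's report-level output)
    t0 = time.perf_counter()
    all_preds = neural.predict_corpus([r.text for r in corpus])
    all_flags = aggregate.flags_for_corpus(
        corpus, predicted_tags=all_preds, min_run=cfg.min_run
    )
    with open(out / "flags.tsv", "w", encoding="utf-8") as fh:
        fh.write("report_id\taphe\tpdph\taphe_criterion\tpdph_criterion\n")
        for rid in sorted(all_flags):
            fl = all_flags[rid]
            fh.write(
                f"{rid}\t{fl.aphe}\t{fl.pdph}\t"
                f"{fl.aphe_provenance.criterion if fl.aphe_provenance else ''}\t"
                f"{fl.pdph_provenance.criterion if fl.pdph_provenance else ''}\n"
            )
    log("aggregate", f"flags for {len(all_flags)} reports", t0)

    # rule-based features ---------------------------------------------
    t0 = time.perf_counter()
    feats = fenlp.features_for_corpus(corpus, lexicon)
    train_ids = {r.report_id for r in train}
    retained = fenlp.build_feature_set(
        {rid: f for rid, f in feats.items() if rid in train_ids},
        min_count=cfg.min_count,
    )
    with open(out / "retained_features.tsv", "w", encoding="utf-8") as fh:
        fh.write("feature\tcount\n")
        for key, count in retained:
            fh.write(f"{key}\t{count}\n")
    log("fenlp", f"{len(retained)} retained features", t0)

    # diagnosis --------------------------------------------------------
    t0 = time.perf_counter()
    matrix = diagnosis.vectorize(corpus, all_flags, feats, retained)
    with open(out / "feature_matrix.tsv", "w", encoding="utf-8") as fh:
        fh.write("report_id\tdiagnosis\t" + "\t".join(matrix.feature_names) + "\n")
        for rid, lab, row in zip(matrix.report_ids, matrix.labels, matrix.X):
            fh.write(
                f"{rid}\t{int(lab)}\t" + "\t".join(str(int(v)) for v in row) + "\n"
            )
    rf_seed = stage_seed(cfg.seed, "diagnosis")
    m_train = matrix.subset_rows([r.report_id for r in train])
    m_test = matrix.subset_rows([r.report_id for r in test])
    subsets = {
        "evidence_only": list(diagnosis.EVIDENCE_COLUMNS),
        "fenlp_only": [k for k, _ in retained],
        "combined": matrix.feature_names,
    }
    diag_metrics: dict = {}
    combined_model: diagnosis.DiagnosisModel | None = None
    for name, cols in subsets.items():
        model = diagnosis.DiagnosisModel(n_trees=cfg.n_trees, seed=rf_seed)
        model.fit(m_train.subset_columns(cols))
        diag_metrics[name] = model.evaluate(m_test.subset_columns(cols))
        if name == "combined":
            combined_model = model

    # corpus-wide frequencies for the ranking eligibility filter
    frequencies = {
        name: int(matrix.X[:, j].sum()) for j, name in enumerate(matrix.feature_names)
    }
    ranking = combined_model.rank(
        frequencies, min_frequency=cfg.min_frequency, top_k=cfg.top_k
    )
    with open(out / "ranking.tsv", "w", encoding="utf-8") as fh:
        fh.write("rank\tfeature\timportance\tfrequency\n")
        for rank, name, score, freq in ranking.top:
            fh.write(f"{rank}\t{name}\t{score:.6f}\t{freq}\n")
    log("diagnose", f"combined F1 {diag_metrics['combined']['f1']:.2f}%", t0)

    # persist ----------------------------------------------------------
    metrics = {"ner": ner_metrics, "diagnosis": diag_metrics}
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2, ensure_ascii=False)
    cfg_dict = json.loads(json.dumps(asdict(cfg)))  # tuples -> lists for YAML
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg_dict, fh, allow_unicode=True, sort_keys=True)
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return PipelineResult(
        config=cfg,
        out_dir=out,
        corpus=corpus,
        train_ids=sorted(r.report_id for r in train),
        test_ids=sorted(r.report_id for r in test),
        ner_metrics=ner_metrics,
        diagnosis_metrics=diag_metrics,
        ranking=ranking,
        retained=retained,
        epoch_losses=list(neural.epoch_losses_),
    )
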