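"""End-to-end orchestration: extract → associate → classify → CNN → interpret.

One validated configuration drives every stage and writes a report bundle:
``features.csv``, one association CSV per label target, a classification
summary CSV (task × model mean∓std AUC), averaged-importance CSVs, an
error-analysis JSON, CNN metrics with extracted saliency patterns, and a
``manifest.json`` recording versions, seeds and content hashes so classical
stages can be reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .corpus_io import read_corpus, read_lexicon, read_metadata, tokenize, \
    write_feature_table
from .dl import CNNConfig, SequenceDatasetConfig, build_sequence_dataset, \
    extract_top_patterns, infer_document, train_cnn
from .features import extract_all, reduce_features
from .ml import MODEL_FAMILIES, ModelSpec, build_strata, error_analysis, \
    repeated_runs, stratified_split
from .stats import association_table


@dataclass
class PipelineConfig:
    corpus_path: str
    metadata_path: str
    lexicon_paths: list
    out_dir: str
    labels: list = field(default_factory=lambda: ["diagnosis"])
    seed: int = 0
    n_runs: int = 100
    power_reps: int = 2000
    model_families: tuple = ("logistic_elasticnet", "random_forest", "ebm")
    run_dl: bool = False
    dl_seq_len: int = 512
    dl_vocab_size: int = 2000
    dl_epochs: int = 50

    def validate(self) -> None:
        for p in [self.corpus_path, self.metadata_path, *self.lexicon_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        bad = set(self.model_families) - set(MODEL_FAMILIES)
        if bad:
            raise ValueError(f"unknown model families {bad}")
        for label in self.labels:
            if label != "diagnosis" and not label.startswith("crit_"):
                raise ValueError(f"unknown label target {label!r}")


def _label_map(metadata, target: str) -> dict:
    if target == "diagnosis":
        return {m.doc_id: int(m.diagnosis in ("full_ptsd", "partial_ptsd"))
                for m in metadata}
    crit = target.removeprefix("crit_")
    return {m.doc_id: int(m.criteria[crit]) for m in metadata}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _assoc_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [{"feature": r.feature, "group": r.group, "test": r.test,
          "p_value": r.p_value, "SE_cohen": r.effect_size, "power": r.power,
          "significant": r.significant} for r in results]
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; partial outputs are retained on failure."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "config": dataclasses.asdict(config), "stages": {},
    }
    stage = "load"
    try:
        t0 = time.time()
        corpus = read_corpus(config.corpus_path)
        metadata = read_metadata(config.metadata_path)
        lexicons = [read_lexicon(p, match_policy="surface")
                    for p in config.lexicon_paths]
        meta_ids = {m.doc_id for m in metadata}
        missing = [t.doc_id for t in corpus if t.doc_id not in meta_ids]
        if missing:
            raise ValueError(f"metadata missing for documents {missing[:5]}")
        docs = [tokenize(t) for t in corpus]
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                     "n_docs": len(docs)}

        stage = "extract"
        t0 = time.time()
        table = extract_all(docs, lexicons)
        write_feature_table(table, out / "features.csv")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                     "n_features": len(table.names)}

        stage = "associate"
        t0 = time.time()
        for target in config.labels:
            labels = _label_map(metadata, target)
            results = association_table(
                table, labels, group_order=[0, 1],
                power_reps=config.power_reps, seed=config.seed)
            _assoc_frame(results).to_csv(out / f"assoc_{target}.csv",
                                         index=False)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "train_ml"
        t0 = time.time()
        reduced = reduce_features(table)
        strata = build_strata(metadata)
        summary_rows = []
        reports: dict = {}
        for target in config.labels:
            labels = _label_map(metadata, target)
            best = None
            for family in config.model_families:
                summary = repeated_runs(
                    ModelSpec(family), reduced, labels, strata,
                    n_runs=config.n_runs, base_seed=config.seed)
                if summary is None:
                    continue
                summary_rows.append(
                    {"task": target, "model": family,
                     "mean_auc": summary.mean_auc, "std_auc": summary.std_auc})
                if best is None or summary.mean_auc > best.mean_auc:
                    best = summary
            if best is not None:
                pd.DataFrame(best.ranked_importances(),
                             columns=["feature", "mean_importance"]).to_csv(
                    out / f"importances_{target}.csv", index=False)
                report = error_analysis(best, metadata, seed=config.seed)
                reports[target] = {
                    "best_model": best.family,
                    "worst_documents": report["worst_documents"],
                    "tests": {k: {"p_value": v.p_value,
                                  "effect_size": v.effect_size,
                                  "power": v.power}
                              for k, v in report["tests"].items()},
                }
        pd.DataFrame(summary_rows).to_csv(out / "ml_summary.csv", index=False)
        (out / "error_analysis.json").write_text(
            json.dumps(reports, indent=1, default=str))
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        if config.run_dl:
            stage = "train_cnn"
            t0 = time.time()
            labels = _label_map(metadata, config.labels[0])
            split = stratified_split(
                [d.doc_id for d in docs], strata, seed=config.seed)
            ds_cfg = SequenceDatasetConfig(
                seq_len=config.dl_seq_len, vocab_size=config.dl_vocab_size,
                seed=config.seed)
            dataset = build_sequence_dataset(docs, labels, ds_cfg, split)
            cnn_cfg = CNNConfig(max_epochs=config.dl_epochs)
            model, log = train_cnn(
                dataset.train, dataset.val,
                {ch: len(dataset.vocab[ch]) for ch in ds_cfg.channels},
                cnn_cfg, seed=config.seed)
            by_id = {d.doc_id: d for d in docs}
            test_ids = sorted({s.doc_id for s in dataset.test})
            doc_probs = {d: infer_document(model, by_id[d], dataset.vocab,
                                           ds_cfg) for d in test_ids}
            from sklearn.metrics import roc_auc_score
            y = [labels[d] for d in test_ids]
            cnn_auc = (float(roc_auc_score(y, [doc_probs[d] for d in test_ids]))
                       if len(set(y)) == 2 else float("nan"))
            positives = [s for s in dataset.test if s.label == 1]
            patterns = extract_top_patterns(model, positives, dataset.vocab) \
                if positives else []
            pd.DataFrame(patterns, columns=["doc_id", "span_text", "channel",
                                            "score"]).to_csv(
                out / "patterns.tsv", sep="\t", index=False)
            (out / "cnn_metrics.json").write_text(json.dumps({
                "test_doc_auc": cnn_auc, "epochs": log.stopped_epoch,
                "val_loss": log.val_loss}, indent=1))
            manifest["stages"][stage] = {
                "seconds": round(time.time() - t0, 2), "auc": cnn_auc}
    except Exception as e:  # annotate failing stage, keep partial outputs
        manifest["error"] = {"stage": stage, "message": str(e)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    manifest["hashes"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
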