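"""End-to-end orchestration: simulate → extract → featurize → train →
evaluate → explain, with provenance and a content-hashed artifact manifest.

Every algorithm is evaluated on the same stratified held-out split, and
the evaluation table has one row per algorithm (baseline, regex+structured,
binary, count, mixed). Two runs with identical config and seed produce
hash-identical manifests.

A single global seed fans out to stage-specific seeds by fixed offsets so
stages can be re-run alone and still reproduce.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import concepts, corpus as corpus_mod, evaluate, features, learn, rules, synth

logger = logging.getLogger(__name__)

ALL_MODELS = ("baseline", "regex-structured", "binary", "count", "mixed")
LEARNED_MODELS = ("binary", "count", "mixed")

_SEED_OFFSETS = {"simulate": 0, "split": 1, "train": 2}


def stage_seed(seed: int, stage: str) -> int:
    return (seed + _SEED_OFFSETS[stage]) % (2**31)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    model: str = "all"  # baseline | regex-structured | binary | count | mixed | all
    corpus_dir: Optional[Path] = None      # load instead of simulating
    synth_config: Optional[synth.SynthConfig] = None
    training: learn.TrainingConfig = field(default_factory=learn.TrainingConfig)
    lexicon_path: Optional[Path] = None
    regex_path: Optional[Path] = None
    negation_path: Optional[Path] = None
    structured_rule_path: Optional[Path] = None
    train_fraction: float = 0.75
    min_encounters: int = 4
    respect_negation: bool = True

    def selected_models(self) -> tuple[str, ...]:
        if self.model == "all":
            return ALL_MODELS
        if self.model not in ALL_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        return (self.model,)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fmt(v) -> str:
    return "" if v is None else f"{v:.6f}"


def _load_resources(config: RunConfig):
    lexicon = (concepts.Lexicon.from_tsv(config.lexicon_path)
               if config.lexicon_path else concepts.Lexicon.default())
    patterns = concepts.load_regex_patterns(config.regex_path)
    neg = (concepts.NegationRules.from_yaml(config.negation_path)
           if config.negation_path else concepts.NegationRules.default())
    rule_cfg = (rules.StructuredRuleConfig.from_yaml(config.structured_rule_path)
                if config.structured_rule_path else rules.StructuredRuleConfig.default())
    return lexicon, patterns, neg, rule_cfg


def run_all(config: RunConfig) -> dict:
    """Run the selected stages end to end; return the artifact manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        lexicon, patterns, neg, rule_cfg = _load_resources(config)

        stage = "simulate"
        if config.corpus_dir is not None:
            cohort = corpus_mod.read_corpus_dir(config.corpus_dir)
        else:
            synth_cfg = config.synth_config or synth.SynthConfig(n_patients=1000)
            synth_cfg.seed = stage_seed(config.seed, "simulate")
            cohort = synth.generate_corpus(synth_cfg)
            paths = corpus_mod.write_corpus(cohort, out_dir / "corpus")
            written += list(paths.values()) + [out_dir / "corpus" / "provenance.json"]
        cohort = corpus_mod.filter_min_encounters(cohort, config.min_encounters)

        stage = "extract"
        cui_counts = features.extract_corpus_cuis(cohort, lexicon, neg)
        regex_hits = {p.patient_id: concepts.match_regex_concepts(
            p, patterns, rules=neg, respect_negation=config.respect_negation)
            for p in cohort.patients}
        extract_path = out_dir / "extraction.json"
        extract_path.write_text(json.dumps(
            {"cui_counts": cui_counts, "regex_hits": regex_hits},
            indent=2, sort_keys=True), encoding="utf-8")
        written.append(extract_path)

        stage = "featurize"
        matrices: dict[str, features.FeatureMatrix] = {}
        selected = config.selected_models()
        if "binary" in selected:
            matrices["binary"] = features.build_cui_matrix(
                cohort, lexicon, neg, mode="binary", cui_counts=cui_counts)
        if "count" in selected:
            matrices["count"] = features.build_cui_matrix(
                cohort, lexicon, neg, mode="count", cui_counts=cui_counts)
        if "mixed" in selected:
            matrices["mixed"] = features.build_mixed_matrix(
                cohort, features.MixedFeatureSpec(), lexicon, neg, patterns,
                rule_cfg, cui_counts=cui_counts, regex_hits=regex_hits)
        feat_dir = out_dir / "features"
        feat_dir.mkdir(exist_ok=True)
        for name, fm in matrices.items():
            fm.save(feat_dir / f"{name}.csv")
            written += [feat_dir / f"{name}.csv", feat_dir / f"{name}.json"]

        stage = "split"
        train_ids, test_ids = evaluate.split_train_test(
            cohort, config.train_fraction, seed=stage_seed(config.seed, "split"))
        labels = {p.patient_id: int(p.gold_label) for p in cohort.labeled()}
        y_test = [labels[pid] for pid in test_ids]

        stage = "train"
        train_cfg = config.training
        train_cfg.seed = stage_seed(config.seed, "train")
        models: dict[str, learn.PenalizedLogisticModel] = {}
        model_dir = out_dir / "models"
        model_dir.mkdir(exist_ok=True)
        for name, fm in matrices.items():
            fm_train = fm.subset_rows(train_ids)
            y_train = [labels[pid] for pid in train_ids]
            best_c, table = learn.grid_search_c(fm_train, y_train, train_cfg)
            model = learn.fit_l2_logreg(fm_train, y_train, best_c, train_cfg)
            model.metadata["grid_search"] = [[c, acc] for c, acc in table]
            model.metadata["seed"] = config.seed
            models[name] = model
            model.to_json(model_dir / f"{name}.json")
            written.append(model_dir / f"{name}.json")

        stage = "evaluate"
        rows = []
        by_id = {p.patient_id: p for p in cohort.patients}
        for name in selected:
            if name == "baseline":
                pred = [int(bool(rules.baseline_classify(by_id[pid], rule_cfg)))
                        for pid in test_ids]
                auc = None
            elif name == "regex-structured":
                pred = [int(bool(rules.regex_structured_classify(
                    by_id[pid], rule_cfg, patterns, rules=neg,
                    respect_negation=config.respect_negation)))
                    for pid in test_ids]
                auc = None
            else:
                fm_test = matrices[name].subset_rows(test_ids)
                proba = learn.predict_proba(models[name], fm_test)
                pred = (proba > train_cfg.threshold).astype(int).tolist()
                auc = evaluate.roc_auc(y_test, proba)
            report = evaluate.metrics(evaluate.confusion(y_test, pred),
                                      threshold=train_cfg.threshold)
            report.auc = auc
            rows.append((name, report))
        eval_path = out_dir / "evaluation.csv"
        with open(eval_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["dataset", "algorithm", "sensitivity", "specificity",
                             "ppv", "npv", "f_measure", "auc"])
            for name, report in rows:
                writer.writerow(["synthetic-test", name, _fmt(report.sensitivity),
                                 _fmt(report.specificity), _fmt(report.ppv),
                                 _fmt(report.npv), _fmt(report.f_measure),
                                 _fmt(report.auc)])
        written.append(eval_path)

        stage = "explain"
        explain_dir = out_dir / "explain"
        explain_dir.mkdir(exist_ok=True)
        for name, model in models.items():
            coef_path = explain_dir / f"{name}_coefficients.csv"
            with open(coef_path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(["feature", "definition", "coefficient"])
                for feat, coef in evaluate.top_coefficients(model, len(model.coef)):
                    writer.writerow([feat, lexicon.cui_definitions.get(feat, ""),
                                     f"{coef:.6f}"])
            fm = matrices[name]
            attribution = evaluate.linear_shap(
                model, fm.subset_rows(test_ids), fm.subset_rows(train_ids))
            shap_path = explain_dir / f"{name}_shap.csv"
            with open(shap_path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(["feature", "mean_abs_shap"])
                for feat, value in attribution.ranking():
                    writer.writerow([feat, f"{value:.6f}"])
            written += [coef_path, shap_path]

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "model": config.model,
            "n_patients": len(cohort.patients),
            "train_size": len(train_ids),
            "test_size": len(test_ids),
            "files": {str(p.relative_to(out_dir)): _sha256(p)
                      for p in sorted(set(written))},
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
        return manifest
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n",
                                        encoding="utf-8")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
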