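"""Feature matrices for the three learned phenotype models.

* full **binary** CUI matrix — one indicator column per CUI positively
  mentioned by at least ``min_document_frequency`` patients (default 30);
* full **count** CUI matrix — same columns but total positive-mention
  counts (default minimum document frequency 40);
* **mixed** 13-feature matrix — 7 curated lupus-nephritis CUI indicators,
  5 regex-concept indicators, and 1 structured-data indicator (the
  baseline rule's output).

"Document frequency" counts patients with at least one positive mention,
the patient being the classification unit; a per-note variant is available
behind ``df_unit="note"``. Features are left unscaled (all mixed features
are 0/1; counts stay raw).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .concepts import (Lexicon, NegationRules, REGEX_CONCEPTS,
                       deduplicate_notes, extract_patient_cuis,
                       match_concepts, match_regex_concepts, split_sentences,
                       apply_negation)
from .corpus import Corpus
from .rules import StructuredRuleConfig, baseline_classify

logger = logging.getLogger(__name__)

DEFAULT_MIXED_CUIS = ("C0024143", "C0268757", "C0268758", "C4053955",
                      "C4053958", "C4053959", "C4054543")
DEFAULT_MIN_DF = {"binary": 30, "count": 40}

FEATURE_KINDS = ("cui_binary", "cui_count", "regex", "structured")


@dataclass
class FeatureMatrix:
    patient_ids: list[str]
    feature_names: list[str]
    kinds: list[str]
    values: np.ndarray  # patients x features, float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids/names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if len(self.kinds) != len(self.feature_names):
            raise ValueError("one kind tag per feature required")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids,
                            columns=self.feature_names)

    def subset_rows(self, patient_ids: Sequence[str]) -> "FeatureMatrix":
        index = {pid: i for i, pid in enumerate(self.patient_ids)}
        rows = [index[pid] for pid in patient_ids]
        return FeatureMatrix(list(patient_ids), list(self.feature_names),
                             list(self.kinds), self.values[rows])

    def save(self, csv_path: str | Path) -> None:
        """CSV (first column patient_id) plus a JSON sidecar of kind tags."""
        csv_path = Path(csv_path)
        df = self.to_dataframe()
        df.index.name = "patient_id"
        df.to_csv(csv_path)
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(json.dumps(
            {"kinds": dict(zip(self.feature_names, self.kinds))},
            indent=2, sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, csv_path: str | Path) -> "FeatureMatrix":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path, index_col="patient_id")
        kinds_map = json.loads(csv_path.with_suffix(".json").read_text("utf-8"))["kinds"]
        return cls([str(i) for i in df.index], list(df.columns),
                   [kinds_map[c] for c in df.columns], df.to_numpy())


@dataclass
class MixedFeatureSpec:
    cuis: tuple[str, ...] = DEFAULT_MIXED_CUIS
    regex_concepts: tuple[str, ...] = REGEX_CONCEPTS
    structured_feature_name: str = "RENAL"

    @property
    def n_features(self) -> int:
        return len(self.cuis) + len(self.regex_concepts) + 1


def extract_corpus_cuis(
    corpus: Corpus, lexicon: Lexicon, rules: NegationRules,
) -> dict[str, dict[str, int]]:
    """Per-patient positive CUI mention counts (cacheable upstream)."""
    return {p.patient_id: extract_patient_cuis(p, lexicon, rules)
            for p in corpus.patients}


def _note_document_frequency(corpus, lexicon, rules) -> dict[str, int]:
    df: dict[str, int] = {}
    for p in corpus.patients:
        for note in deduplicate_notes(p.notes):
            note_cuis: set[str] = set()
            for si, sent in enumerate(split_sentences(note.text)):
                mentions = match_concepts(sent.text, lexicon)
                for m in apply_negation(sent.text, mentions, rules):
                    if not m.negated:
                        note_cuis.add(m.cui)
            for cui in note_cuis:
                df[cui] = df.get(cui, 0) + 1
    return df


def build_cui_matrix(
    corpus: Corpus,
    lexicon: Lexicon,
    rules: NegationRules,
    mode: str = "binary",
    min_document_frequency: Optional[int] = None,
    cui_counts: Optional[Mapping[str, Mapping[str, int]]] = None,
    df_unit: str = "patient",
) -> FeatureMatrix:
    """Full CUI feature matrix in binary or count mode.

    Columns are the CUIs positively mentioned in at least
    ``min_document_frequency`` documents (patients by default), sorted for
    determinism. A corpus smaller than the frequency floor yields an empty
    matrix with a logged warning.
    """
    if mode not in ("binary", "count"):
        raise ValueError(f"mode must be 'binary' or 'count', got {mode!r}")
    min_df = DEFAULT_MIN_DF[mode] if min_document_frequency is None else min_document_frequency
    if min_df < 0:
        raise ValueError("min_document_frequency must be >= 0")
    if cui_counts is None:
        cui_counts = extract_corpus_cuis(corpus, lexicon, rules)

    if df_unit == "patient":
        df: dict[str, int] = {}
        for counts in cui_counts.values():
            for cui in counts:
                df[cui] = df.get(cui, 0) + 1
    elif df_unit == "note":
        df = _note_document_frequency(corpus, lexicon, rules)
    else:
        raise ValueError(f"df_unit must be 'patient' or 'note', got {df_unit!r}")

    kept = sorted(cui for cui, n in df.items() if n >= min_df)
    if not kept and len(corpus.patients) < min_df:
        logger.warning("corpus of %d patients is smaller than min_document_frequency=%d; "
                       "empty feature matrix", len(corpus.patients), min_df)

    pids = [p.patient_id for p in corpus.patients]
    values = np.zeros((len(pids), len(kept)))
    col = {cui: j for j, cui in enumerate(kept)}
    for i, pid in enumerate(pids):
        for cui, n in cui_counts.get(pid, {}).items():
            if cui in col:
                values[i, col[cui]] = 1.0 if mode == "binary" else float(n)
    kind = "cui_binary" if mode == "binary" else "cui_count"
    return FeatureMatrix(pids, kept, [kind] * len(kept), values)


def build_mixed_matrix(
    corpus: Corpus,
    spec: MixedFeatureSpec,
    lexicon: Lexicon,
    rules: NegationRules,
    patterns: Mapping[str, Sequence],
    structured_config: StructuredRuleConfig,
    cui_counts: Optional[Mapping[str, Mapping[str, int]]] = None,
    regex_hits: Optional[Mapping[str, Mapping[str, int]]] = None,
    respect_negation: bool = True,
) -> FeatureMatrix:
    """The 13-feature mixed representation, columns in spec order.

    CUI columns are binary positive-mention indicators for the curated
    CUIs (no document-frequency filter); regex columns are binary hit
    indicators; the final structured column is the baseline rule's 0/1
    output. Column count is constant regardless of corpus content.
    """
    if cui_counts is None:
        cui_counts = extract_corpus_cuis(corpus, lexicon, rules)
    if regex_hits is None:
        regex_hits = {p.patient_id: match_regex_concepts(
            p, patterns, rules=rules, respect_negation=respect_negation)
            for p in corpus.patients}

    pids = [p.patient_id for p in corpus.patients]
    names = (list(spec.cuis) + list(spec.regex_concepts)
             + [spec.structured_feature_name])
    kinds = (["cui_binary"] * len(spec.cuis) + ["regex"] * len(spec.regex_concepts)
             + ["structured"])
    values = np.zeros((len(pids), len(names)))
    for i, patient in enumerate(corpus.patients):
        counts = cui_counts.get(patient.patient_id, {})
        for j, cui in enumerate(spec.cuis):
            values[i, j] = 1.0 if counts.get(cui, 0) > 0 else 0.0
        hits = regex_hits.get(patient.patient_id, {})
        for j, concept in enumerate(spec.regex_concepts):
            values[i, len(spec.cuis) + j] = 1.0 if hits.get(concept, 0) > 0 else 0.0
        values[i, -1] = 1.0 if baseline_classify(patient, structured_config) else 0.0
    return FeatureMatrix(pids, names, kinds, values)
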