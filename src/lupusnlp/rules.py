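"""Rule-based lupus nephritis classifiers.

Two rules share one configuration:

* **baseline** — structured data only: positive iff the patient has a
  urine-protein lab strictly above the threshold (0.5 on the
  protein/creatinine-ratio scale, equivalently 500 mg per 24 h) or a
  lupus-nephritis ICD-9/10 diagnosis code; optionally a positive
  red-blood-cell-cast result (the SLICC renal criterion's second arm,
  off by default).
* **regex + structured** — positive iff the baseline fires or any of the
  five nephritis regex concepts hits in the patient's notes.

The shipped diagnosis-code sets are reconstructed defaults and fully
editable; the rule logic depends only on set membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .concepts import NegationRules, match_regex_concepts
from .corpus import PatientRecord

logger = logging.getLogger(__name__)

_SCALE_TO_KIND = {
    "ratio": "urine_protein_creatinine_ratio",
    "grams_per_24h": "urine_protein_24h_g",
}


@dataclass
class StructuredRuleConfig:
    ln_icd9_codes: frozenset = frozenset()
    ln_icd10_codes: frozenset = frozenset()
    proteinuria_threshold: float = 0.5
    proteinuria_scale: str = "ratio"
    use_rbc_casts: bool = False

    def __post_init__(self) -> None:
        self.ln_icd9_codes = frozenset(self.ln_icd9_codes)
        self.ln_icd10_codes = frozenset(self.ln_icd10_codes)
        if self.proteinuria_threshold <= 0:
            raise ValueError("proteinuria_threshold must be > 0")
        if self.proteinuria_scale not in _SCALE_TO_KIND:
            raise ValueError(f"unknown proteinuria_scale {self.proteinuria_scale!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StructuredRuleConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            ln_icd9_codes=frozenset(raw.get("ln_icd9_codes", ())),
            ln_icd10_codes=frozenset(raw.get("ln_icd10_codes", ())),
            proteinuria_threshold=float(raw.get("proteinuria_threshold", 0.5)),
            proteinuria_scale=raw.get("proteinuria_scale", "ratio"),
            use_rbc_casts=bool(raw.get("use_rbc_casts", False)),
        )

    @classmethod
    def default(cls) -> "StructuredRuleConfig":
        path = resources.files("lupusnlp.data").joinpath("structured_rule.yaml")
        with resources.as_file(path) as p:
            return cls.from_yaml(p)


@dataclass
class RuleDecision:
    positive: bool
    fired: list[str] = field(default_factory=list)  # subset of {lab, dx, rbc_casts, regex}

    def __bool__(self) -> bool:
        return self.positive


def baseline_classify(patient: PatientRecord,
                      config: StructuredRuleConfig) -> RuleDecision:
    """Structured-data rule: qualifying lab OR lupus-nephritis code.

    The lab comparison is strict (``> threshold``); labs on a different
    protein scale than configured are skipped with a logged warning.
    """
    fired: list[str] = []
    wanted_kind = _SCALE_TO_KIND[config.proteinuria_scale]
    for lab in patient.structured.labs:
        if lab.kind == "rbc_casts_present":
            if config.use_rbc_casts and bool(lab.value):
                if "rbc_casts" not in fired:
                    fired.append("rbc_casts")
            continue
        if lab.kind != wanted_kind:
            logger.warning("patient %s: lab %s does not match configured scale %s; skipped",
                           patient.patient_id, lab.kind, config.proteinuria_scale)
            continue
        if float(lab.value) > config.proteinuria_threshold and "lab" not in fired:
            fired.append("lab")
    for system, code in patient.structured.diagnosis_codes:
        code_set = config.ln_icd9_codes if system == "ICD9" else config.ln_icd10_codes
        if code in code_set:
            fired.append("dx")
            break
    return RuleDecision(positive=bool(fired), fired=fired)


def regex_structured_classify(
    patient: PatientRecord,
    config: StructuredRuleConfig,
    patterns: Mapping[str, Sequence],
    rules: NegationRules | None = None,
    respect_negation: bool = True,
) -> RuleDecision:
    """Baseline rule OR any nephritis regex concept hit in the notes."""
    decision = baseline_classify(patient, config)
    hits = match_regex_concepts(patient, patterns, rules=rules,
                                respect_negation=respect_negation)
    if any(v > 0 for v in hits.values()):
        decision.fired.append("regex")
        decision.positive = True
    return decision
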