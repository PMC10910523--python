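import pytest

from lupusnlp import (Lexicon, NegationRules, StructuredRuleConfig,
                      load_regex_patterns)
from lupusnlp.corpus import (ClinicalNote, Corpus, LabResult, PatientRecord,
                             StructuredRecord)
from lupusnlp.synth import SynthConfig, generate_corpus_with_log


@pytest.fixture(scope="session")
def lexicon():
    return Lexicon.default()


@pytest.fixture(scope="session")
def negation_rules():
    return NegationRules.default()


@pytest.fixture(scope="session")
def patterns():
    return load_regex_patterns()


@pytest.fixture(scope="session")
def rule_config():
    return StructuredRuleConfig.default()


def make_patient(pid="p1", texts=(), codes=(), labs=(), label=None,
                 encounter_count=None):
    """One patient with one note per text; convenience for unit tests."""
    notes = [
        ClinicalNote(note_id=f"{pid}-n{i}", patient_id=pid, note_type="progress",
                     department="nephrology", date=f"2020-01-{i + 1:02d}", text=t)
        for i, t in enumerate(texts)
    ]
    structured = StructuredRecord(
        patient_id=pid, diagnosis_codes=set(codes),
        labs=[LabResult(pid, kind, value, "2020-06-01") for kind, value in labs])
    return PatientRecord(
        patient_id=pid, notes=notes, structured=structured,
        encounter_count=len(notes) if encounter_count is None else encounter_count,
        gold_label=label)


@pytest.fixture
def tiny_corpus():
    """Hand-written 2-patient corpus with unicode text and labs/codes."""
    p1 = make_patient(
        "alpha",
        texts=["Biopsy confirmed lupus nephritis. Suivi régulier — naïve à 37.5°C.",
               "Vital signs stable."],
        codes={("ICD10", "M32.14")},
        labs=[("urine_protein_creatinine_ratio", 0.8)],
        label=True)
    p2 = make_patient(
        "beta",
        texts=["No evidence of lupus nephritis."],
        labs=[("urine_protein_creatinine_ratio", 0.2)],
        label=False)
    return Corpus(patients=[p1, p2], provenance="hand-written fixture")


@pytest.fixture(scope="session")
def small_generated():
    """40-patient generated corpus plus the planted-signal log."""
    config = SynthConfig(n_patients=40, notes_mean=10, notes_sd=6, seed=7)
    corpus, logs = generate_corpus_with_log(config)
    return corpus, logs
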