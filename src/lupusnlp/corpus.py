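"""Domain types and on-disk formats for patient-level EHR bundles.

A :class:`Corpus` holds one :class:`PatientRecord` per patient: free-text
clinical notes, structured diagnosis codes and laboratory results, a stored
encounter count, and an optional chart-review gold label for lupus nephritis.

On disk a corpus is three plain-text files in one directory:

* ``notes.jsonl`` — one JSON object per note with keys ``note_id``,
  ``patient_id``, ``note_type``, ``department``, ``date``, ``text``.
* ``structured.csv`` — rows ``patient_id, record_kind, system, code,
  lab_kind, value, date`` with ``record_kind`` one of ``dx``, ``lab`` or
  ``encounter_count`` (the last stores the patient's encounter tally so the
  write→read round trip reproduces every field).
* ``labels.csv`` — ``patient_id, lupus_nephritis`` (0/1); optional, and
  rows are written only for labeled patients.

Dates are ISO-8601 day strings; there is no timezone or time-of-day logic
anywhere downstream, so they are kept as plain strings and compared
lexicographically.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

NOTE_TYPES = ("pathology", "progress", "consult", "discharge")
DEPARTMENTS = ("transplant", "nephrology", "rheumatology", "other")
LAB_KINDS = (
    "urine_protein_creatinine_ratio",
    "urine_protein_24h_g",
    "rbc_casts_present",
)
CODE_SYSTEMS = ("ICD9", "ICD10")

# Syntactic shape only — membership in phenotype code sets is configured
# elsewhere (phenotype rules).
_ICD9_RE = re.compile(r"^[VE]?\d{2,3}(\.\d{1,2})?$")
_ICD10_RE = re.compile(r"^[A-TV-Z]\d[0-9A-Z](\.[0-9A-Z]{1,4})?$")

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


class CorpusError(ValueError):
    """Invalid corpus content or malformed corpus file."""


def _format_error(path, line, field_name, message) -> CorpusError:
    return CorpusError(f"{path}:{line}: field '{field_name}': {message}")


@dataclass
class ClinicalNote:
    note_id: str
    patient_id: str
    note_type: str
    department: str
    date: str
    text: str


@dataclass
class LabResult:
    patient_id: str
    kind: str
    value: float | bool
    date: str


@dataclass
class StructuredRecord:
    patient_id: str
    diagnosis_codes: set[tuple[str, str]] = field(default_factory=set)
    labs: list[LabResult] = field(default_factory=list)


@dataclass
class PatientRecord:
    patient_id: str
    notes: list[ClinicalNote] = field(default_factory=list)
    structured: StructuredRecord | None = None
    encounter_count: int = 0
    gold_label: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.structured is None:
            self.structured = StructuredRecord(patient_id=self.patient_id)

    @property
    def distinct_note_dates(self) -> int:
        return len({n.date for n in self.notes})


@dataclass
class Corpus:
    patients: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.patients)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def labeled(self) -> list[PatientRecord]:
        return [p for p in self.patients if p.gold_label is not None]


def validate_corpus(corpus: Corpus) -> None:
    """Check structural invariants; raise :class:`CorpusError` on violation."""
    seen_pid: set[str] = set()
    seen_nid: set[str] = set()
    for p in corpus.patients:
        if p.patient_id in seen_pid:
            raise CorpusError(f"duplicate patient_id {p.patient_id!r}")
        seen_pid.add(p.patient_id)
        if p.encounter_count < 0:
            raise CorpusError(f"{p.patient_id}: negative encounter_count")
        if p.encounter_count < p.distinct_note_dates:
            raise CorpusError(
                f"{p.patient_id}: encounter_count {p.encounter_count} < "
                f"{p.distinct_note_dates} distinct note dates"
            )
        for n in p.notes:
            if n.note_id in seen_nid:
                raise CorpusError(f"duplicate note_id {n.note_id!r}")
            seen_nid.add(n.note_id)
            if not n.text.strip():
                raise CorpusError(f"note {n.note_id}: empty text")
            if n.note_type not in NOTE_TYPES:
                raise CorpusError(f"note {n.note_id}: bad note_type {n.note_type!r}")
            if n.department not in DEPARTMENTS:
                raise CorpusError(f"note {n.note_id}: bad department {n.department!r}")
        for system, code in p.structured.diagnosis_codes:
            pattern = _ICD9_RE if system == "ICD9" else _ICD10_RE
            if system not in CODE_SYSTEMS:
                raise CorpusError(f"{p.patient_id}: unknown code system {system!r}")
            if not pattern.match(code):
                raise CorpusError(f"{p.patient_id}: malformed {system} code {code!r}")
        for lab in p.structured.labs:
            if lab.kind not in LAB_KINDS:
                raise CorpusError(f"{p.patient_id}: unknown lab kind {lab.kind!r}")
            if lab.kind != "rbc_casts_present" and float(lab.value) < 0:
                raise CorpusError(f"{p.patient_id}: negative lab value {lab.value}")


def read_corpus(
    notes_path: str | Path,
    structured_path: str | Path,
    labels_path: str | Path | None = None,
) -> Corpus:
    """Assemble a :class:`Corpus` from its three on-disk files.

    Patients appear in the order of first mention in ``structured.csv``
    (every written corpus carries one ``encounter_count`` row per patient),
    then any note-only patients in note order. Patients with no notes are
    retained with an empty note list. A label for an unknown patient is an
    error.
    """
    notes_path = Path(notes_path)
    structured_path = Path(structured_path)

    order: list[str] = []
    records: dict[str, PatientRecord] = {}

    def ensure(pid: str) -> PatientRecord:
        if pid not in records:
            records[pid] = PatientRecord(patient_id=pid)
            order.append(pid)
        return records[pid]

    with open(structured_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"patient_id", "record_kind"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise _format_error(structured_path, 1, "header", "missing required columns")
        for lineno, row in enumerate(reader, start=2):
            pid = (row.get("patient_id") or "").strip()
            if not pid:
                raise _format_error(structured_path, lineno, "patient_id", "empty")
            kind = (row.get("record_kind") or "").strip()
            patient = ensure(pid)
            if kind == "dx":
                system = (row.get("system") or "").strip()
                code = (row.get("code") or "").strip()
                if system not in CODE_SYSTEMS:
                    raise _format_error(structured_path, lineno, "system",
                                        f"unknown code system {system!r}")
                if not code:
                    raise _format_error(structured_path, lineno, "code", "empty")
                patient.structured.diagnosis_codes.add((system, code))
            elif kind == "lab":
                lab_kind = (row.get("lab_kind") or "").strip()
                if lab_kind not in LAB_KINDS:
                    raise _format_error(structured_path, lineno, "lab_kind",
                                        f"unknown lab kind {lab_kind!r}")
                raw = (row.get("value") or "").strip()
                if lab_kind == "rbc_casts_present":
                    value: float | bool = raw in ("1", "True", "true")
                else:
                    try:
                        value = float(raw)
                    except ValueError:
                        raise _format_error(structured_path, lineno, "value",
                                            f"not a number: {raw!r}") from None
                    if value < 0:
                        raise _format_error(structured_path, lineno, "value",
                                            f"negative lab value {value}")
                patient.structured.labs.append(
                    LabResult(pid, lab_kind, value, (row.get("date") or "").strip())
                )
            elif kind == "encounter_count":
                raw = (row.get("value") or "").strip()
                try:
                    patient.encounter_count = int(raw)
                except ValueError:
                    raise _format_error(structured_path, lineno, "value",
                                        f"not an integer: {raw!r}") from None
            else:
                raise _format_error(structured_path, lineno, "record_kind",
                                    f"unknown record_kind {kind!r}")

    note_counted: set[str] = set()
    with open(notes_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise _format_error(notes_path, lineno, "-", f"invalid JSON: {exc}") from None
            for key in ("note_id", "patient_id", "note_type", "department", "date", "text"):
                if key not in obj:
                    raise _format_error(notes_path, lineno, key, "missing")
            patient = ensure(obj["patient_id"])
            patient.notes.append(
                ClinicalNote(
                    note_id=obj["note_id"],
                    patient_id=obj["patient_id"],
                    note_type=obj["note_type"],
                    department=obj["department"],
                    date=obj["date"],
                    text=obj["text"],
                )
            )
            note_counted.add(obj["patient_id"])

    # Loader fallback: a corpus written by hand may omit encounter_count
    # rows; the stored count then defaults to the distinct-note-date floor.
    for p in records.values():
        if p.encounter_count == 0 and p.notes:
            p.encounter_count = p.distinct_note_dates

    if labels_path is not None:
        labels_path = Path(labels_path)
        with open(labels_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                pid = (row.get("patient_id") or "").strip()
                if pid not in records:
                    raise _format_error(labels_path, lineno, "patient_id",
                                        f"label for unknown patient {pid!r}")
                raw = (row.get("lupus_nephritis") or "").strip()
                if raw not in ("0", "1"):
                    raise _format_error(labels_path, lineno, "lupus_nephritis",
                                        f"expected 0 or 1, got {raw!r}")
                records[pid].gold_label = raw == "1"

    provenance = f"files:{notes_path}"
    prov_file = notes_path.parent / "provenance.json"
    if prov_file.exists():
        provenance = prov_file.read_text(encoding="utf-8").strip()

    corpus = Corpus(patients=[records[pid] for pid in order], provenance=provenance)
    validate_corpus(corpus)
    return corpus


def write_corpus(corpus: Corpus, out_dir: str | Path) -> dict[str, Path]:
    """Write the three corpus files (plus provenance.json) into ``out_dir``.

    Round trip: ``read_corpus(**write_corpus(c))`` reproduces ``c``
    field-for-field, including unicode note text byte-exactly.
    """
    validate_corpus(corpus)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    notes_path = out_dir / "notes.jsonl"
    structured_path = out_dir / "structured.csv"
    labels_path = out_dir / "labels.csv"

    with open(notes_path, "w", encoding="utf-8") as fh:
        for p in corpus.patients:
            for n in p.notes:
                fh.write(json.dumps({
                    "note_id": n.note_id,
                    "patient_id": n.patient_id,
                    "note_type": n.note_type,
                    "department": n.department,
                    "date": n.date,
                    "text": n.text,
                }, ensure_ascii=False) + "\n")

    with open(structured_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "record_kind", "system", "code",
                         "lab_kind", "value", "date"])
        for p in corpus.patients:
            writer.writerow([p.patient_id, "encounter_count", "", "", "",
                             p.encounter_count, ""])
            for system, code in sorted(p.structured.diagnosis_codes):
                writer.writerow([p.patient_id, "dx", system, code, "", "", ""])
            for lab in p.structured.labs:
                value = int(lab.value) if lab.kind == "rbc_casts_present" else lab.value
                writer.writerow([p.patient_id, "lab", "", "", lab.kind, value, lab.date])

    any_labels = any(p.gold_label is not None for p in corpus.patients)
    paths = {"notes_path": notes_path, "structured_path": structured_path}
    with open(labels_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "lupus_nephritis"])
        if any_labels:
            for p in corpus.patients:
                if p.gold_label is not None:
                    writer.writerow([p.patient_id, int(p.gold_label)])
    if any_labels:
        paths["labels_path"] = labels_path

    (out_dir / "provenance.json").write_text(corpus.provenance, encoding="utf-8")
    return paths


def read_corpus_dir(corpus_dir: str | Path) -> Corpus:
    """Read a corpus from a directory written by :func:`write_corpus`."""
    corpus_dir = Path(corpus_dir)
    labels = corpus_dir / "labels.csv"
    labels_path = None
    if labels.exists():
        with open(labels, encoding="utf-8") as fh:
            if len(fh.readlines()) > 1:
                labels_path = labels
    return read_corpus(corpus_dir / "notes.jsonl", corpus_dir / "structured.csv",
                       labels_path)


def filter_min_encounters(corpus: Corpus, min_encounters: int = 4) -> Corpus:
    """Keep patients with ``encounter_count >= min_encounters`` (order kept).

    The cohort-depth filter: patients with fewer than four documented
    clinical encounters lack the data depth the phenotyping algorithms
    assume, and are excluded before any text processing.
    """
    if min_encounters < 0:
        raise ValueError("min_encounters must be >= 0")
    kept = [p for p in corpus.patients if p.encounter_count >= min_encounters]
    return Corpus(patients=kept, provenance=corpus.provenance)
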