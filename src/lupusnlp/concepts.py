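"""Note preprocessing and clinical concept extraction.

This is the package's stand-in for a full UMLS concept mapper: notes are
deduplicated, split into sentences, scanned against a phrase→CUI lexicon
(case-insensitive, longest match wins), and each mention is assigned a
negation flag by a NegEx-style forward trigger scan. A separate
regular-expression channel finds the five nephritis text concepts
(histologic classes II–V and quantified proteinuria).

Unlike a plain keyword search, the regex channel is negation-aware by
default: a pattern hit whose start falls inside the forward scope of a
negation trigger ("negative renal disorder: either persistent proteinuria
(> 0.5 g/day or + + +) or cellular casts") is suppressed. Passing
``respect_negation=False`` reproduces the naive behavior for comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import yaml

from .corpus import ClinicalNote, PatientRecord

REGEX_CONCEPTS = (
    "nephritis_class_II",
    "nephritis_class_III",
    "nephritis_class_IV",
    "nephritis_class_V",
    "proteinuria",
)

_WORD_RE = re.compile(r"\w+")


def _data_path(name: str):
    return resources.files("lupusnlp.data").joinpath(name)


# ---------------------------------------------------------------------------
# Lexicon


@dataclass
class Lexicon:
    """Surface phrase → CUI mapping plus CUI glosses.

    Phrases are matched case-insensitively with flexible internal
    whitespace; overlapping matches resolve to the longest phrase.
    """

    entries: dict[str, str]
    cui_definitions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {k.lower().strip(): v for k, v in self.entries.items()}
        if any(not p for p in self.entries):
            raise ValueError("lexicon phrases must be non-empty")
        self._pattern = _compile_phrase_pattern(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        entries: dict[str, str] = {}
        definitions: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected phrase<TAB>CUI[<TAB>definition]")
                phrase, cui = parts[0], parts[1]
                entries[phrase] = cui
                if len(parts) > 2 and parts[2]:
                    definitions.setdefault(cui, parts[2])
        return cls(entries=entries, cui_definitions=definitions)

    @classmethod
    def default(cls) -> "Lexicon":
        with resources.as_file(_data_path("lexicon.tsv")) as path:
            return cls.from_tsv(path)


def _compile_phrase_pattern(entries: Mapping[str, str]) -> re.Pattern:
    # Longest-first alternation => at any start position the regex engine
    # prefers the longest phrase, which implements longest-match-wins.
    phrases = sorted(entries, key=lambda p: (-len(p), p))
    parts = [re.escape(p).replace(r"\ ", r"\s+").replace(" ", r"\s+") for p in phrases]
    return re.compile(r"\b(?:" + "|".join(parts) + r")\b", re.IGNORECASE)


class ConceptMention(NamedTuple):
    patient_id: str
    note_id: str
    sentence_index: int
    cui: str
    matched_text: str
    start: int  # 0-based, within sentence
    end: int    # half-open
    negated: bool = False


class RegexConceptHit(NamedTuple):
    patient_id: str
    note_id: str
    concept: str
    matched_text: str
    start: int
    end: int


# ---------------------------------------------------------------------------
# Negation rules


@dataclass
class NegationRules:
    pre_triggers: tuple[str, ...]
    pseudo_triggers: tuple[str, ...]
    scope_window: int = 6

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")
        if not self.pre_triggers:
            raise ValueError("pre_triggers must be non-empty")
        self.pre_triggers = tuple(t.lower() for t in self.pre_triggers)
        self.pseudo_triggers = tuple(t.lower() for t in self.pseudo_triggers)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NegationRules":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            pre_triggers=tuple(raw["pre_triggers"]),
            pseudo_triggers=tuple(raw.get("pseudo_triggers", ())),
            scope_window=int(raw.get("scope_window", 6)),
        )

    @classmethod
    def default(cls) -> "NegationRules":
        with resources.as_file(_data_path("negation.yaml")) as path:
            return cls.from_yaml(path)


# ---------------------------------------------------------------------------
# Preprocessing


def normalize_text(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip()).lower()


def deduplicate_notes(notes: Sequence[ClinicalNote]) -> list[ClinicalNote]:
    """Collapse notes with identical normalized text (one patient's notes).

    Among duplicates the earliest-dated note wins; date ties break to the
    lowest note_id. Relative order of the survivors is preserved.
    """
    best: dict[str, ClinicalNote] = {}
    for note in notes:
        key = normalize_text(note.text)
        cur = best.get(key)
        if cur is None or (note.date, note.note_id) < (cur.date, cur.note_id):
            best[key] = note
    keep = {id(n) for n in best.values()}
    return [n for n in notes if id(n) in keep]


class Sentence(NamedTuple):
    text: str
    start: int  # offset of sentence text in source
    end: int


_ABBREVIATIONS = {"dr", "mr", "mrs", "ms", "st", "vs", "e.g", "i.e", "etc",
                  "approx", "fig", "ref", "al", "wt", "pt"}
# Boundary: terminal punctuation followed by whitespace/end (a period inside
# a decimal number is followed by a digit and never qualifies), or a blank
# line.
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)|\n[ \t]*\n")


def split_sentences(text: str) -> list[Sentence]:
    """Split text into sentences with source offsets.

    Splits at ``.``, ``!``, ``?`` and blank lines; a short abbreviation
    list (``Dr.``, ``vs.``, ``e.g.`` ...) and decimal numbers are
    protected. The sentence spans cover every non-whitespace character of
    the input exactly once.
    """
    if not text.strip():
        return []
    cuts: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        if m.group().strip(".!?") == "" and "." in m.group():
            prev = re.search(r"(\S+)$", text[: m.start()])
            if prev and prev.group(1).lower().rstrip(".") in _ABBREVIATIONS:
                continue
        cuts.append(m.end())
    sentences: list[Sentence] = []
    prev_end = 0
    for cut in cuts + [len(text)]:
        if cut <= prev_end:
            continue
        chunk = text[prev_end:cut]
        stripped = chunk.strip()
        if stripped:
            start = prev_end + len(chunk) - len(chunk.lstrip())
            sentences.append(Sentence(stripped, start, start + len(stripped)))
        prev_end = cut
    return sentences


# ---------------------------------------------------------------------------
# Concept matching and negation


def match_concepts(
    sentence: str,
    lexicon: Lexicon,
    *,
    patient_id: str = "",
    note_id: str = "",
    sentence_index: int = 0,
) -> list[ConceptMention]:
    """Scan one sentence for lexicon phrases (longest match wins).

    Matches are non-overlapping; a shorter phrase nested inside a longer
    match is suppressed. The negation flag is left False.
    """
    mentions: list[ConceptMention] = []
    for m in lexicon._pattern.finditer(sentence):
        key = normalize_text(m.group())
        cui = lexicon.entries.get(key)
        if cui is None:  # defensive: pattern and entries built together
            continue
        mentions.append(ConceptMention(patient_id, note_id, sentence_index,
                                       cui, m.group(), m.start(), m.end()))
    return mentions


def _token_spans(sentence: str) -> list[tuple[int, int, str]]:
    return [(m.start(), m.end(), m.group().lower()) for m in _WORD_RE.finditer(sentence)]


def _negated_token_checker(sentence: str, rules: NegationRules):
    """Return f(char_start) -> bool for spans in this sentence."""
    tokens = _token_spans(sentence)
    words = [t[2] for t in tokens]

    def occurrences(phrase: str) -> list[tuple[int, int]]:
        seq = phrase.split()
        hits = []
        for i in range(len(words) - len(seq) + 1):
            if words[i : i + len(seq)] == seq:
                hits.append((i, i + len(seq) - 1))
        return hits

    pseudo_spans = [span for p in rules.pseudo_triggers for span in occurrences(p)]
    trigger_ends: list[int] = []
    for trig in rules.pre_triggers:
        for (s, e) in occurrences(trig):
            if any(ps <= s and e <= pe for ps, pe in pseudo_spans):
                continue
            trigger_ends.append(e)

    def is_negated(char_start: int) -> bool:
        mention_tok = None
        for i, (ts, te, _) in enumerate(tokens):
            if ts <= char_start < te or ts >= char_start:
                mention_tok = i
                break
        if mention_tok is None:
            return False
        return any(e < mention_tok and mention_tok - e <= rules.scope_window
                   for e in trigger_ends)

    return is_negated


def apply_negation(
    sentence: str,
    mentions: Sequence[ConceptMention],
    rules: NegationRules,
) -> list[ConceptMention]:
    """Set the negated flag on mentions of one sentence.

    A mention is negated iff a pre-trigger ends within ``scope_window``
    word tokens before the mention start, and that trigger occurrence is
    not part of a pseudo-trigger phrase. Deterministic.
    """
    is_negated = _negated_token_checker(sentence, rules)
    return [m._replace(negated=is_negated(m.start)) for m in mentions]


def extract_patient_cuis(
    patient: PatientRecord,
    lexicon: Lexicon,
    rules: NegationRules,
) -> dict[str, int]:
    """Positive (non-negated) mention count per CUI for one patient.

    Pipeline: deduplicate notes → split sentences → lexicon match →
    negation scoping. CUIs with zero positive mentions are absent.
    """
    counts: dict[str, int] = {}
    for note in deduplicate_notes(patient.notes):
        for si, sent in enumerate(split_sentences(note.text)):
            mentions = match_concepts(sent.text, lexicon,
                                      patient_id=patient.patient_id,
                                      note_id=note.note_id, sentence_index=si)
            if not mentions:
                continue
            for m in apply_negation(sent.text, mentions, rules):
                if not m.negated:
                    counts[m.cui] = counts.get(m.cui, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Regex concept channel


class RegexPatternError(ValueError):
    """A concept pattern failed to compile."""


def load_regex_patterns(path: str | Path | None = None) -> dict[str, list[re.Pattern]]:
    """Load concept → compiled pattern lists (case-insensitive).

    An invalid pattern raises :class:`RegexPatternError` naming the
    concept at load time.
    """
    if path is None:
        with resources.as_file(_data_path("regex_concepts.yaml")) as p:
            return load_regex_patterns(p)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    compiled: dict[str, list[re.Pattern]] = {}
    for concept, patterns in raw.items():
        compiled[concept] = []
        for pat in patterns:
            try:
                compiled[concept].append(re.compile(pat, re.IGNORECASE))
            except re.error as exc:
                raise RegexPatternError(
                    f"concept {concept!r}: invalid pattern {pat!r}: {exc}") from None
    return compiled


def match_regex_concepts(
    patient: PatientRecord,
    patterns: Mapping[str, Sequence[re.Pattern]],
    rules: NegationRules | None = None,
    respect_negation: bool = True,
) -> dict[str, int]:
    """Hit count per regex concept over a patient's deduplicated notes.

    With ``respect_negation=True`` (default) matching runs per sentence
    and hits inside a negation-trigger scope are suppressed; with False
    the patterns run over raw note text, reproducing the naive keyword
    behavior that asserts "proteinuria (> 0.5" even inside a negated
    criterion sentence.
    """
    if respect_negation and rules is None:
        rules = NegationRules.default()
    counts = {concept: 0 for concept in patterns}
    for note in deduplicate_notes(patient.notes):
        if respect_negation:
            for sent in split_sentences(note.text):
                checker = None
                for concept, pats in patterns.items():
                    for pat in pats:
                        for m in pat.finditer(sent.text):
                            if checker is None:
                                checker = _negated_token_checker(sent.text, rules)
                            if not checker(m.start()):
                                counts[concept] += 1
        else:
            for concept, pats in patterns.items():
                for pat in pats:
                    counts[concept] += sum(1 for _ in pat.finditer(note.text))
    return counts
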