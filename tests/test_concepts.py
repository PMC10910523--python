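"""Concept extraction: dedup, sentence splitting, lexicon matching,
negation scoping, and the regex concept channel."""

import re

import pytest

from lupusnlp.concepts import (Lexicon, NegationRules, RegexPatternError,
                               apply_negation, deduplicate_notes,
                               extract_patient_cuis, match_concepts,
                               match_regex_concepts, normalize_text,
                               split_sentences)
from lupusnlp.corpus import ClinicalNote
from lupusnlp.synth import BOILERPLATE_SENTENCE

from conftest import make_patient


def note(nid, text, date="2020-01-01"):
    return ClinicalNote(note_id=nid, patient_id="p", note_type="progress",
                        department="nephrology", date=date, text=text)


class TestDeduplication:
    def test_byte_identical_notes_collapse(self):
        notes = [note("a", "Stable."), note("b", "Stable.", date="2020-02-01")]
        kept = deduplicate_notes(notes)
        assert [n.note_id for n in kept] == ["a"]  # earliest date wins

    def test_whitespace_and_case_variants_are_duplicates(self):
        notes = [note("a", "Renal  Biopsy \n done."),
                 note("b", "renal biopsy done.", date="2019-01-01")]
        kept = deduplicate_notes(notes)
        assert [n.note_id for n in kept] == ["b"]

    def test_distinct_notes_survive(self):
        distinct = [note(f"d{i}", f"Finding number {i}.") for i in range(5)]
        copies = [note(f"c{i}", "Finding number 0.", date="2021-01-01")
                  for i in range(3)]
        assert len(deduplicate_notes(distinct + copies)) == 5

    def test_date_tie_breaks_to_lowest_note_id(self):
        notes = [note("b", "Same."), note("a", "Same.")]
        assert [n.note_id for n in deduplicate_notes(notes)] == ["a"]


class TestSentenceSplitting:
    @pytest.mark.parametrize("text,expected", [
        ("Pt has LN. Proteinuria 0.8 g/day.", 2),
        ("", 0),
        ("   \n ", 0),
        ("One! Two? Three.", 3),
        ("First paragraph\n\nSecond paragraph", 2),
        ("Symptoms, e.g. rash, were absent. Next visit.", 2),
        ("Seen by Dr. Smith today. Stable.", 2),
    ])
    def test_sentence_counts(self, text, expected):
        assert len(split_sentences(text)) == expected

    def test_decimal_numbers_not_split(self):
        sents = split_sentences("Ratio of 0.8 noted. Next.")
        assert [s.text for s in sents] == ["Ratio of 0.8 noted.", "Next."]

    @pytest.mark.parametrize("text", [
        "Pt has LN. Proteinuria 0.8 g/day.",
        "A.\n\nB and C! D?",
        "  padded   text with   gaps. Second.  ",
    ])
    def test_spans_cover_non_whitespace_exactly_once(self, text):
        sents = split_sentences(text)
        rebuilt = "".join(text[s.start:s.end] for s in sents)
        assert "".join(rebuilt.split()) == "".join(text.split())
        for s in sents:
            assert text[s.start:s.end] == s.text


class TestLexiconMatching:
    def test_longest_match_wins(self):
        lex = Lexicon(entries={"lupus nephritis": "C0024143",
                               "nephritis": "C0027697"})
        mentions = match_concepts("biopsy confirmed lupus nephritis", lex)
        assert [(m.cui, m.matched_text) for m in mentions] == \
            [("C0024143", "lupus nephritis")]

    def test_no_hit_is_empty(self, lexicon):
        assert match_concepts("unremarkable visit", lexicon) == []

    def test_default_lexicon_two_concepts(self, lexicon):
        cuis = [m.cui for m in match_concepts("nephritis and proteinuria", lexicon)]
        assert cuis == ["C0027697", "C0033687"]

    def test_span_matches_matched_text(self, lexicon):
        sent = "Known LUPUS  NEPHRITIS history"
        (m,) = match_concepts(sent, lexicon)
        assert normalize_text(sent[m.start:m.end]) == "lupus nephritis"

    def test_every_referenced_cui_has_definition(self, lexicon):
        for cui in set(lexicon.entries.values()):
            assert cui in lexicon.cui_definitions


class TestNegation:
    def negated_flags(self, sentence, lexicon, rules):
        mentions = match_concepts(sentence, lexicon)
        return {m.cui: m.negated for m in apply_negation(sentence, mentions, rules)}

    def test_no_glomerulonephritis_is_negated(self, lexicon, negation_rules):
        flags = self.negated_flags("no glomerulonephritis", lexicon, negation_rules)
        assert flags == {"C0027697": True}

    def test_trigger_after_span_does_not_negate(self, lexicon, negation_rules):
        flags = self.negated_flags("lupus nephritis, no rash", lexicon, negation_rules)
        assert flags["C0024143"] is False

    def test_boilerplate_criterion_sentence_fully_negated(self, lexicon, negation_rules):
        # Known failure mode of naive keyword search: the whole SLICC
        # criterion is denied at the start of the sentence.
        flags = self.negated_flags(BOILERPLATE_SENTENCE, lexicon, negation_rules)
        assert flags == {"C0022658": True, "C0033687": True}

    def test_trigger_outside_window_does_not_negate(self, lexicon):
        rules = NegationRules(pre_triggers=("no",), pseudo_triggers=(), scope_window=2)
        sent = "no relevant prior renal history of proteinuria"
        flags = self.negated_flags(sent, lexicon, rules)
        assert flags["C0033687"] is False

    def test_pseudo_trigger_overrides(self, lexicon, negation_rules):
        flags = self.negated_flags("no increase in proteinuria", lexicon,
                                   negation_rules)
        assert flags["C0033687"] is False


class TestRegexConcepts:
    def test_canonical_class_phrase(self, patterns, negation_rules):
        p = make_patient(texts=["Biopsy showed nephritis class IV."])
        hits = match_regex_concepts(p, patterns, rules=negation_rules)
        assert hits["nephritis_class_IV"] == 1
        assert hits["nephritis_class_II"] == 0

    def test_stage_2_ln_paraphrase(self, patterns, negation_rules):
        p = make_patient(texts=["The patient had stage 2 LN per outside records."])
        hits = match_regex_concepts(p, patterns, rules=negation_rules)
        assert hits["nephritis_class_II"] == 1

    def test_empty_notes_all_zero(self, patterns, negation_rules):
        p = make_patient(texts=())
        assert all(v == 0 for v in
                   match_regex_concepts(p, patterns, rules=negation_rules).values())

    def test_negation_aware_vs_naive_on_boilerplate(self, patterns, negation_rules):
        p = make_patient(texts=[BOILERPLATE_SENTENCE])
        fixed = match_regex_concepts(p, patterns, rules=negation_rules)
        naive = match_regex_concepts(p, patterns, respect_negation=False)
        assert fixed["proteinuria"] == 0
        assert naive["proteinuria"] == 1

    def test_invalid_pattern_errors_at_load(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("proteinuria:\n  - '([unclosed'\n")
        from lupusnlp.concepts import load_regex_patterns
        with pytest.raises(RegexPatternError, match="proteinuria"):
            load_regex_patterns(bad)


class TestPatientExtraction:
    def test_only_negated_mention_yields_empty(self, lexicon, negation_rules):
        p = make_patient(texts=["No evidence of lupus nephritis."])
        assert extract_patient_cuis(p, lexicon, negation_rules) == {}

    def test_counts_exclude_negated(self, lexicon, negation_rules):
        p = make_patient(texts=[
            "Biopsy confirmed lupus nephritis.",
            "Lupus nephritis stable today.",
            "Clinic follow up of lupus nephritis.",
            "No evidence of lupus nephritis on repeat biopsy."])
        assert extract_patient_cuis(p, lexicon, negation_rules) == {"C0024143": 3}

    def test_generator_bookkeeping_is_reproduced(self, small_generated, lexicon,
                                                 negation_rules, patterns):
        corpus, logs = small_generated
        for p in corpus.patients:
            log = logs[p.patient_id]
            assert extract_patient_cuis(p, lexicon, negation_rules) == log.cui_counts
            hits = {k: v for k, v in
                    match_regex_concepts(p, patterns, rules=negation_rules).items()
                    if v}
            assert hits == log.regex_counts

    def test_extraction_invariant_to_note_order_and_duplicates(
            self, lexicon, negation_rules):
        p = make_patient(texts=["Biopsy confirmed lupus nephritis.",
                                "Mild proteinuria observed."])
        base = extract_patient_cuis(p, lexicon, negation_rules)
        shuffled = make_patient(texts=["Mild proteinuria observed.",
                                       "Biopsy confirmed lupus nephritis."])
        assert extract_patient_cuis(shuffled, lexicon, negation_rules) == base
        doubled = make_patient(texts=["Biopsy confirmed lupus nephritis.",
                                      "Mild proteinuria observed.",
                                      "Biopsy confirmed lupus nephritis."])
        assert extract_patient_cuis(doubled, lexicon, negation_rules) == base

    def test_naive_recount_oracle_agrees(self, small_generated, lexicon,
                                         negation_rules):
        """Brute-force per-sentence recount, written independently of the
        extraction pipeline, must agree on small corpora."""
        corpus, _ = small_generated
        phrases = sorted(lexicon.entries, key=len, reverse=True)
        for p in corpus.patients[:25]:
            counts: dict[str, int] = {}
            seen_texts = {}
            for n in sorted(p.notes, key=lambda n: (n.date, n.note_id)):
                key = " ".join(n.text.lower().split())
                if key in seen_texts:
                    continue
                seen_texts[key] = n
            for n in seen_texts.values():
                for raw in re.split(r"(?<=[.!?])\s+", n.text):
                    sent = raw.lower()
                    taken = [False] * len(sent)
                    for phrase in phrases:
                        for m in re.finditer(r"\b" + re.escape(phrase) + r"\b", sent):
                            if any(taken[m.start():m.end()]):
                                continue
                            for i in range(m.start(), m.end()):
                                taken[i] = True
                            words_before = sent[:m.start()].split()
                            window = words_before[-negation_rules.scope_window:]
                            window = [re.sub(r"\W+", "", w) for w in window]
                            negated = any(
                                w in ("no", "not", "denies", "denied", "without",
                                      "negative") for w in window)
                            if not negated:
                                cui = lexicon.entries[phrase]
                                counts[cui] = counts.get(cui, 0) + 1
            assert counts == extract_patient_cuis(p, lexicon, negation_rules)
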