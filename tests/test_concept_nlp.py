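from datetime import date

import numpy as np
import pytest

from apinlp.concept_nlp import (
    Lexicon,
    classify_cold_sense,
    extract_mentions,
    match_concepts,
    split_sentences,
)
from apinlp.sectioner import segment
from apinlp.synthetic_corpus import COLD_SENSE_TEMPLATES, FILLER_SENTENCES

from conftest import make_note, make_patient


# ---------------------------------------------------------------------------
# Sentence splitting


def _oracle_split(text):
    """Independent character-scan splitter mirroring the documented rule."""
    abbrevs = {
        "dr", "mr", "mrs", "ms", "jr", "sr", "vs", "etc", "approx",
        "dept", "appt", "wk", "wks", "yr", "yrs", "mos", "e.g", "i.e",
    }
    spans, start, i, n = [], 0, 0, len(text)
    while i < n:
        c = text[i]
        end_here = False
        if c in "\n!?":
            end_here = True
        elif c == ".":
            prev_word = ""
            j = i - 1
            while j >= 0 and (text[j].isalpha() or text[j] == "."):
                prev_word = text[j] + prev_word
                j -= 1
            decimal = 0 < i < n - 1 and text[i - 1].isdigit() and text[i + 1].isdigit()
            end_here = not decimal and prev_word.rstrip(".").lower() not in abbrevs
        if end_here:
            j = i + 1
            while j < n and text[j] in ".!?)\"'":
                j += 1
            while j < n and text[j] in " \t\n":
                j += 1
            spans.append((start, j))
            start = i = j
        else:
            i += 1
    if start < n:
        spans.append((start, n))
    return spans


@pytest.mark.parametrize(
    "text,expected_n",
    [
        ("No wheezing. Eczema noted.", 2),
        ("", 0),
        ("One sentence only", 1),
        ("Line one\nline two", 2),
        ("Temp 37.5 stable. Next visit.", 2),  # decimal must not split
        ("Seen by Dr. Smith today. Doing well.", 2),  # abbreviation guard
    ],
)
def test_split_sentences_examples(text, expected_n):
    spans = split_sentences(text)
    assert len(spans) == expected_n
    assert "".join(text[a:b] for a, b in spans) == text


def test_split_sentences_matches_oracle_on_generated_texts():
    rng = np.random.default_rng(3)
    pieces = [
        "No wheezing today.", "Eczema noted!", "Is it viral?", "Temp 38.2 recorded.",
        "Seen by Dr. Smith.", "plain fragment", "HPI: cough\n", "Two lines\nhere.",
    ]
    for _ in range(300):
        k = int(rng.integers(0, 6))
        text = " ".join(pieces[int(rng.integers(len(pieces)))] for _ in range(k))
        assert split_sentences(text) == _oracle_split(text)


def test_split_spans_tile_text_on_corpus_notes(clean_corpus):
    corpus, _, _ = clean_corpus
    for rec in corpus[:20]:
        for note in rec.notes:
            spans = split_sentences(note.text)
            assert "".join(note.text[a:b] for a, b in spans) == note.text


# ---------------------------------------------------------------------------
# Concept matching


def test_simple_wheeze_match(lexicon, header_rules):
    note = make_note("HPI: audible wheezing tonight.")
    secs = segment(note, header_rules)
    mentions = match_concepts(secs, lexicon, note)
    assert [m.concept for m in mentions] == ["WHEEZE"]
    assert note.text[mentions[0].start : mentions[0].end].lower() == "wheezing"


def test_unlisted_surface_form_does_not_match(lexicon, header_rules):
    note = make_note("HPI: rhinorrhea and congestion.")
    mentions = match_concepts(segment(note, header_rules), lexicon, note)
    assert mentions == []


def test_overlapping_matches_merge_to_longest(lexicon, header_rules):
    note = make_note("HPI: recovering from a common cold.")
    mentions = match_concepts(segment(note, header_rules), lexicon, note)
    colds = [m for m in mentions if m.concept == "COLD"]
    assert len(colds) == 1
    assert colds[0].text.lower() == "common cold"


def test_matching_is_whole_word(lexicon, header_rules):
    # "scold", "colder" must not hit the COLD pattern
    note = make_note("HPI: do not scold him; weather got colder.")
    mentions = match_concepts(segment(note, header_rules), lexicon, note)
    assert mentions == []


def test_planted_pattern_count_recovered(lexicon, header_rules):
    rng = np.random.default_rng(8)
    plants = ["wheezing", "eczema", "hay fever", "asthma"]
    concepts = ["WHEEZE", "ECZEMA", "ALLERGIC_RHINITIS", "ASTHMA"]
    for _ in range(50):
        k = int(rng.integers(0, 8))
        chosen = [int(rng.integers(len(plants))) for _ in range(k)]
        body = []
        for idx in chosen:
            body.append(f"Documented {plants[idx]} again.")
            body.append(FILLER_SENTENCES[int(rng.integers(len(FILLER_SENTENCES)))])
        note = make_note("HPI: " + " ".join(body) if body else "HPI: quiet visit.")
        mentions = match_concepts(segment(note, header_rules), lexicon, note)
        expected = sorted(concepts[i] for i in chosen)
        assert sorted(m.concept for m in mentions) == expected


# ---------------------------------------------------------------------------
# Assertion status


def _assert_of(text, lexicon, concept="WHEEZE"):
    patient = make_patient(notes=[make_note(text)])
    mentions = [m for m in extract_mentions(patient, lexicon) if m.concept == concept]
    assert len(mentions) >= 1
    return mentions[0].assertion


@pytest.mark.parametrize(
    "sentence,polarity,temporality,experiencer",
    [
        ("HPI: no wheezing or coughing.", "negated", "current", "patient"),
        ("HPI: denies wheezing.", "negated", "current", "patient"),
        ("HPI: wheezing without relief.", "affirmed", "current", "patient"),
        ("HPI: no fever but wheezing persists.", "affirmed", "current", "patient"),
        ("HPI: return if wheezing recurs.", "affirmed", "hypothetical", "patient"),
        ("HPI: watch for wheezing at night.", "affirmed", "hypothetical", "patient"),
        ("HPI: audible wheezing tonight.", "affirmed", "current", "patient"),
    ],
)
def test_wheeze_assertion_cases(lexicon, sentence, polarity, temporality, experiencer):
    a = _assert_of(sentence, lexicon)
    assert (a.polarity, a.temporality, a.experiencer) == (
        polarity,
        temporality,
        experiencer,
    )


def test_mother_asthma_is_family_parent(lexicon):
    a = _assert_of("FAMILY HISTORY: mother has asthma.", lexicon, "ASTHMA")
    assert a.polarity == "affirmed" and a.experiencer == "family_parent"


def test_sibling_asthma_is_family_other(lexicon):
    a = _assert_of("FAMILY HISTORY: older brother has asthma.", lexicon, "ASTHMA")
    assert a.experiencer == "family_other"


def test_unattributed_family_history_mention_modes():
    lenient = Lexicon.default()
    strict = Lexicon.default(strict_parent_attribution=True)
    text = "FAMILY HISTORY: asthma."
    a_len = _assert_of(text, lenient, "ASTHMA")
    a_str = _assert_of(text, strict, "ASTHMA")
    assert a_len.experiencer == "family_parent"
    assert a_str.experiencer == "family_other"


def test_parent_term_outside_family_section_still_attributes(lexicon):
    a = _assert_of("HPI: father has asthma too.", lexicon, "ASTHMA")
    assert a.experiencer == "family_parent"


def test_negation_scope_does_not_cross_sentences(lexicon):
    a = _assert_of("HPI: No fever. Wheezing again today.", lexicon)
    assert a.polarity == "affirmed"


def test_template_bank_assertions_match_plan(lexicon):
    """500 generated sentences with known (trigger, gap, terminator) plans."""
    rng = np.random.default_rng(17)
    neg = ["no", "without", "denies"]
    hyp = ["rule out", "watch for"]
    fillers = [
        "mild", "intermittent", "nocturnal", "recent",
        "occasional", "persistent", "further", "new",
    ]
    window = lexicon.scope_window_tokens
    for _ in range(500):
        kind = ["none", "neg", "hyp"][int(rng.integers(3))]
        gap = int(rng.integers(0, 9))
        terminator = bool(rng.integers(2)) and gap >= 1
        words = [fillers[int(rng.integers(len(fillers)))] for _ in range(gap)]
        if terminator:
            words[int(rng.integers(len(words)))] = "but"
        prefix = ""
        if kind == "neg":
            prefix = neg[int(rng.integers(len(neg)))] + " "
        elif kind == "hyp":
            prefix = hyp[int(rng.integers(len(hyp)))] + " "
        sentence = "HPI: " + prefix + " ".join(words + ["wheezing", "noted."])
        in_scope = gap <= window and not terminator
        want_pol = "negated" if kind == "neg" and in_scope else "affirmed"
        want_tmp = "hypothetical" if kind == "hyp" and in_scope else "current"
        a = _assert_of(sentence, lexicon)
        assert (a.polarity, a.temporality) == (want_pol, want_tmp), sentence


# ---------------------------------------------------------------------------
# "cold" sense disambiguation


def test_cold_sense_examples(lexicon):
    patient = make_patient(
        notes=[
            make_note("HPI: wheezing triggered by cold air.", note_id="a"),
            make_note("HPI: wheezing with a head cold.", note_id="b"),
        ]
    )
    senses = {
        m.note_id: m.sense
        for m in extract_mentions(patient, lexicon)
        if m.concept == "COLD"
    }
    assert senses == {"a": "temperature_or_other", "b": "illness"}


def test_cold_sense_template_bank_recovery(lexicon):
    assert len(COLD_SENSE_TEMPLATES) >= 40
    assert {lab for _, lab in COLD_SENSE_TEMPLATES} == {
        "illness",
        "temperature_or_other",
    }
    hits = 0
    total = 0
    for sentence, label in COLD_SENSE_TEMPLATES:
        patient = make_patient(notes=[make_note("HPI: " + sentence)])
        colds = [
            m for m in extract_mentions(patient, lexicon) if m.concept == "COLD"
        ]
        assert colds, sentence
        total += 1
        if colds[0].sense == label:
            hits += 1
    assert hits / total >= 0.95


def test_cold_sense_rejects_non_cold_mentions(lexicon):
    patient = make_patient(notes=[make_note("HPI: audible wheezing.")])
    (m,) = extract_mentions(patient, lexicon)
    with pytest.raises(ValueError):
        classify_cold_sense(m, "audible wheezing.")


# ---------------------------------------------------------------------------
# Full extraction


def test_extract_simple_eczema_note(lexicon):
    patient = make_patient(notes=[make_note("IMPRESSION: eczema.")])
    (m,) = extract_mentions(patient, lexicon)
    assert m.concept == "ECZEMA"
    assert m.section_type == "diagnosis_impression"
    assert m.assertion.is_affirmed_current_patient
    assert m.date == patient.notes[0].date


def test_extract_no_notes_no_mentions(lexicon):
    assert extract_mentions(make_patient(), lexicon) == []


def test_extraction_is_deterministic(lexicon, noisy_corpus):
    corpus, _, _ = noisy_corpus
    for rec in corpus[:10]:
        assert extract_mentions(rec, lexicon) == extract_mentions(rec, lexicon)


def test_appending_note_preserves_existing_mentions(lexicon, noisy_corpus):
    corpus, _, _ = noisy_corpus
    rec = next(r for r in corpus if len(r.notes) >= 2)
    before = extract_mentions(rec, lexicon)
    grown = rec.model_copy(deep=True)
    grown.notes.append(
        make_note("HPI: new wheezing today.", date(2009, 12, 1), "zz-new")
    )
    after = extract_mentions(grown, lexicon)
    assert [m for m in after if m.note_id != "zz-new"] == before


def test_filler_templates_contain_no_concepts(lexicon, header_rules):
    from apinlp.synthetic_corpus import (
        FILLER_SENTENCES,
        SAFE_IMPRESSIONS,
    )

    for s in FILLER_SENTENCES + SAFE_IMPRESSIONS:
        note = make_note("HPI: " + s)
        assert match_concepts(segment(note, header_rules), lexicon, note) == []
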