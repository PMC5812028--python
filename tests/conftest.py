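from datetime import date

import pytest

from apinlp.concept_nlp import Lexicon
from apinlp.corpus_model import ClinicalNote, PatientRecord
from apinlp.sectioner import default_header_rules
from apinlp.synthetic_corpus import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def lexicon():
    return Lexicon.default()


@pytest.fixture(scope="session")
def header_rules():
    return default_header_rules()


def make_patient(patient_id="P1", birth=date(2003, 1, 1), notes=(), labs=(), ppi=()):
    return PatientRecord(
        patient_id=patient_id,
        birth_date=birth,
        notes=list(notes),
        labs=list(labs),
        ppi=list(ppi),
    )


def make_note(text, d=date(2005, 6, 1), note_id="n1"):
    return ClinicalNote(note_id=note_id, date=d, text=text)


@pytest.fixture(scope="session")
def clean_corpus():
    """Distractor-free 200-patient corpus with its truth and gold labels."""
    cfg = SynthConfig(n_patients=200, seed=7, target_prevalence=0.10).distractor_free()
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def noisy_corpus():
    """Corpus with all distractor channels active."""
    cfg = SynthConfig(n_patients=120, seed=13, target_prevalence=0.12)
    return generate_corpus(cfg)
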