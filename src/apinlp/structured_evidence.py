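"""Evidence for API criteria from non-narrative sources: eosinophil
differentials (labs) and parental-asthma questionnaire answers (PPI),
plus parental asthma asserted in family-history note text.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

from .concept_nlp import ConceptMention
from .corpus_model import Analyte, LabResult, PPIRecord, YesNoUnknown

__all__ = [
    "DEFAULT_EOS_THRESHOLD_PCT",
    "EosinophiliaEvent",
    "ParentalAsthmaEvidence",
    "eosinophilia_events",
    "parental_asthma_events",
]

# API minor criterion: blood eosinophils at or above 4 percent
DEFAULT_EOS_THRESHOLD_PCT = 4.0


@dataclass(frozen=True)
class EosinophiliaEvent:
    date: date
    value_pct: float
    qualifies: bool


@dataclass(frozen=True)
class ParentalAsthmaEvidence:
    date: date
    source: str  # "ppi" | "family_history_text"
    parent: str  # "mother" | "father" | "unspecified_parent"


def eosinophilia_events(
    labs: Iterable[LabResult],
    threshold_pct: float = DEFAULT_EOS_THRESHOLD_PCT,
) -> list[EosinophiliaEvent]:
    """One event per eosinophil-percentage lab, flagged against the threshold.

    The threshold is boundary-inclusive (a value exactly at threshold
    qualifies).  Absolute eosinophil counts are ignored: the criterion is
    defined on the percentage scale and no unit conversion is attempted.
    Results are eligible regardless of test indication.
    """
    if not (0 < threshold_pct <= 100):
        raise ValueError("threshold_pct must be in (0, 100]")
    events = [
        EosinophiliaEvent(
            date=lab.date,
            value_pct=lab.value,
            qualifies=lab.value >= threshold_pct,
        )
        for lab in labs
        if lab.analyte is Analyte.eosinophil_pct
    ]
    events.sort(key=lambda e: e.date)
    return events


_MOTHER = ("mother", "mom", "maternal", "mother's")
_FATHER = ("father", "dad", "paternal", "father's")


def _parent_from_sentence(sentence: str) -> str:
    low = sentence.lower()
    if any(t in low for t in _MOTHER):
        return "mother"
    if any(t in low for t in _FATHER):
        return "father"
    return "unspecified_parent"


def parental_asthma_events(
    ppi: Iterable[PPIRecord],
    family_mentions: Sequence[ConceptMention],
    note_texts: dict[str, str] | None = None,
) -> list[ParentalAsthmaEvidence]:
    """Union of parental-asthma evidence from PPI yes-answers and from
    affirmed, current, parent-experiencer ASTHMA mentions in note text.

    ``family_mentions`` must already be restricted to concept=ASTHMA with
    experiencer=family_parent, affirmed, current (enforced here).
    Deduplicated by (date, parent, source).
    """
    out: set[ParentalAsthmaEvidence] = set()
    for rec in ppi:
        if rec.value is YesNoUnknown.yes:
            parent = "mother" if rec.field.value == "mother_asthma" else "father"
            out.add(ParentalAsthmaEvidence(rec.date, "ppi", parent))
    for m in family_mentions:
        if m.concept != "ASTHMA":
            continue
        a = m.assertion
        if a is None or a.polarity != "affirmed" or a.temporality != "current":
            continue
        if a.experiencer != "family_parent":
            continue
        sentence = ""
        if note_texts and m.note_id in note_texts:
            sentence = note_texts[m.note_id][m.sentence_start : m.sentence_end]
        out.add(
            ParentalAsthmaEvidence(
                m.date, "family_history_text", _parent_from_sentence(sentence)
            )
        )
    return sorted(out, key=lambda e: (e.date, e.source, e.parent))
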