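"""Patient classification: aggregate evidence into per-criterion timelines
and decide Asthma Predictive Index status and index date.

The rule: a child is API-positive if they have frequent wheezing episodes
(at least two episodes within one year) together with at least one major
criterion (parental physician-diagnosed asthma; patient eczema) or at
least two minor criteria (patient allergic rhinitis; wheezing apart from
colds; blood eosinophils >= 4%).  The index date is the earliest calendar
date on which the accumulated evidence satisfies the whole rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

from .concept_nlp import ConceptMention, Lexicon, extract_mentions
from .corpus_model import PatientRecord
from .sectioner import HeaderRule
from .structured_evidence import (
    DEFAULT_EOS_THRESHOLD_PCT,
    EosinophiliaEvent,
    ParentalAsthmaEvidence,
    eosinophilia_events,
    parental_asthma_events,
)

__all__ = [
    "CRITERIA",
    "MAJOR_CRITERIA",
    "MINOR_CRITERIA",
    "APIRuleConfig",
    "CriterionEvidence",
    "APIResult",
    "wheeze_episode_dates",
    "frequent_wheeze_date",
    "wheeze_apart_from_cold_date",
    "criterion_timeline",
    "classify_api",
    "classify_patient",
    "classify_corpus",
    "results_to_jsonl",
    "read_results",
]

MAJOR_CRITERIA = ("MAJ_PARENT_ASTHMA", "MAJ_ECZEMA")
MINOR_CRITERIA = ("MIN_ALLERGIC_RHINITIS", "MIN_WHEEZE_APART_FROM_COLD", "MIN_EOSINOPHILIA")
CRITERIA = ("FREQ_WHEEZE",) + MAJOR_CRITERIA + MINOR_CRITERIA


@dataclass(frozen=True)
class APIRuleConfig:
    """Tunable parameters of the API rule (defaults are the published rule)."""

    wheeze_window_days: int = 365
    min_episodes: int = 2
    min_major: int = 1
    min_minor: int = 2
    eos_threshold_pct: float = DEFAULT_EOS_THRESHOLD_PCT
    episode_collapse: str = "per_calendar_date"
    evidence_timing: str = "on_or_before_candidate_date"
    strict_diagnosis_section: bool = False

    def __post_init__(self) -> None:
        if self.wheeze_window_days <= 0:
            raise ValueError("wheeze_window_days must be positive")
        if min(self.min_episodes, self.min_major, self.min_minor) < 1:
            raise ValueError("criterion counts must be >= 1")


@dataclass(frozen=True)
class CriterionEvidence:
    criterion: str
    satisfied_date: Optional[date]
    support: tuple = ()

    def __post_init__(self) -> None:
        if (self.satisfied_date is None) != (len(self.support) == 0):
            raise ValueError("satisfied_date present iff support non-empty")


@dataclass
class APIResult:
    patient_id: str
    status: str  # positive | negative
    index_date: Optional[date]
    criteria: list[CriterionEvidence] = field(default_factory=list)
    majors_met: int = 0
    minors_met: int = 0
    error: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "status": self.status,
            "index_date": self.index_date.isoformat() if self.index_date else None,
            "majors_met": self.majors_met,
            "minors_met": self.minors_met,
            "criteria": [
                {
                    "criterion": c.criterion,
                    "satisfied_date": (
                        c.satisfied_date.isoformat() if c.satisfied_date else None
                    ),
                    "support": list(c.support),
                }
                for c in self.criteria
            ],
            "error": self.error,
        }


# ---------------------------------------------------------------------------
# Wheeze episodes and temporal windows


def wheeze_episode_dates(mentions: Iterable[ConceptMention]) -> list[date]:
    """Distinct calendar dates with an affirmed, current, patient wheeze.

    Same-day duplicate documentation collapses to a single episode.
    """
    dates = {
        m.date
        for m in mentions
        if m.concept == "WHEEZE"
        and m.assertion is not None
        and m.assertion.is_affirmed_current_patient
    }
    return sorted(dates)


def frequent_wheeze_date(
    episode_dates: Sequence[date], config: APIRuleConfig = APIRuleConfig()
) -> Optional[date]:
    """Earliest date d with >= min_episodes episodes in the closed trailing
    window [d - wheeze_window_days, d]; the window is boundary-inclusive,
    so two episodes exactly one year apart qualify.
    """
    dates = sorted(set(episode_dates))
    k = config.min_episodes
    win = timedelta(days=config.wheeze_window_days)
    for j in range(k - 1, len(dates)):
        if dates[j] - dates[j - k + 1] <= win:
            return dates[j]
    return None


def wheeze_apart_from_cold_date(
    wheeze_mentions: Sequence[ConceptMention],
    cold_mentions: Sequence[ConceptMention],
) -> Optional[date]:
    """Earliest date of a wheeze episode whose source note has no
    illness-sense cold mention.

    A temperature-sense "cold" ("wheezing triggered by cold air") does not
    disqualify the note, and a negated cold ("wheezing, no URI symptoms")
    counts in favour of wheezing apart from colds.
    """
    cold_notes = {
        m.note_id
        for m in cold_mentions
        if m.concept == "COLD"
        and m.sense == "illness"
        and m.assertion is not None
        and m.assertion.is_affirmed_current_patient
    }
    qualifying = [
        m.date
        for m in wheeze_mentions
        if m.concept == "WHEEZE"
        and m.assertion is not None
        and m.assertion.is_affirmed_current_patient
        and m.note_id not in cold_notes
    ]
    return min(qualifying) if qualifying else None


# ---------------------------------------------------------------------------
# Criterion timeline


def _earliest_patient_mention(
    mentions: Sequence[ConceptMention],
    concept: str,
    strict_diagnosis_section: bool,
) -> list[ConceptMention]:
    hits = [
        m
        for m in mentions
        if m.concept == concept
        and m.assertion is not None
        and m.assertion.is_affirmed_current_patient
        and (not strict_diagnosis_section or m.section_type == "diagnosis_impression")
    ]
    hits.sort(key=lambda m: (m.date, m.note_id, m.start))
    return hits


def criterion_timeline(
    patient: PatientRecord,
    mentions: Sequence[ConceptMention],
    eos_events: Sequence[EosinophiliaEvent],
    parental_events: Sequence[ParentalAsthmaEvidence],
    config: APIRuleConfig = APIRuleConfig(),
) -> list[CriterionEvidence]:
    """Earliest satisfaction date per API criterion, with supporting refs."""
    out: list[CriterionEvidence] = []

    wheeze = [m for m in mentions if m.concept == "WHEEZE"]
    cold = [m for m in mentions if m.concept == "COLD"]

    episodes = wheeze_episode_dates(wheeze)
    fw = frequent_wheeze_date(episodes, config)
    out.append(
        CriterionEvidence(
            "FREQ_WHEEZE",
            fw,
            tuple(f"wheeze_episode:{d.isoformat()}" for d in episodes if fw and d <= fw),
        )
    )

    if parental_events:
        first = min(parental_events, key=lambda e: e.date)
        out.append(
            CriterionEvidence(
                "MAJ_PARENT_ASTHMA",
                first.date,
                (f"{first.source}:{first.parent}:{first.date.isoformat()}",),
            )
        )
    else:
        out.append(CriterionEvidence("MAJ_PARENT_ASTHMA", None))

    for criterion, concept in (
        ("MAJ_ECZEMA", "ECZEMA"),
        ("MIN_ALLERGIC_RHINITIS", "ALLERGIC_RHINITIS"),
    ):
        hits = _earliest_patient_mention(
            mentions, concept, config.strict_diagnosis_section
        )
        if hits:
            m = hits[0]
            out.append(
                CriterionEvidence(
                    criterion, m.date, (f"note:{m.note_id}:{m.start}-{m.end}",)
                )
            )
        else:
            out.append(CriterionEvidence(criterion, None))

    wafc = wheeze_apart_from_cold_date(wheeze, cold)
    out.append(
        CriterionEvidence(
            "MIN_WHEEZE_APART_FROM_COLD",
            wafc,
            (f"wheeze_episode:{wafc.isoformat()}",) if wafc else (),
        )
    )

    qual = [e for e in eos_events if e.qualifies]
    if qual:
        first_lab = min(qual, key=lambda e: e.date)
        out.append(
            CriterionEvidence(
                "MIN_EOSINOPHILIA",
                first_lab.date,
                (f"lab:eos={first_lab.value_pct}:{first_lab.date.isoformat()}",),
            )
        )
    else:
        out.append(CriterionEvidence("MIN_EOSINOPHILIA", None))
    return out


# ---------------------------------------------------------------------------
# Classification


def classify_api(
    timeline: Sequence[CriterionEvidence],
    config: APIRuleConfig = APIRuleConfig(),
    patient_id: str = "",
) -> APIResult:
    """Decide status and index date from a criterion timeline.

    Index date = earliest date d such that FREQ_WHEEZE is satisfied on or
    before d and, counting criteria satisfied on or before d, at least
    min_major majors or min_minor minors hold.  Candidates range over the
    finitely many satisfaction dates.
    """
    by_name = {c.criterion: c for c in timeline}
    fw = by_name["FREQ_WHEEZE"].satisfied_date

    def counts_at(d: date) -> tuple[int, int]:
        majors = sum(
            1
            for name in MAJOR_CRITERIA
            if by_name[name].satisfied_date is not None
            and by_name[name].satisfied_date <= d
        )
        minors = sum(
            1
            for name in MINOR_CRITERIA
            if by_name[name].satisfied_date is not None
            and by_name[name].satisfied_date <= d
        )
        return majors, minors

    index_date: Optional[date] = None
    majors_met = minors_met = 0
    if fw is not None:
        candidates = sorted(
            {c.satisfied_date for c in timeline if c.satisfied_date is not None}
        )
        for d in candidates:
            if fw <= d:
                majors, minors = counts_at(d)
                if majors >= config.min_major or minors >= config.min_minor:
                    index_date = d
                    majors_met, minors_met = majors, minors
                    break

    return APIResult(
        patient_id=patient_id,
        status="positive" if index_date is not None else "negative",
        index_date=index_date,
        criteria=list(timeline),
        majors_met=majors_met,
        minors_met=minors_met,
    )


def classify_patient(
    patient: PatientRecord,
    lexicon: Optional[Lexicon] = None,
    config: APIRuleConfig = APIRuleConfig(),
    header_rules: Optional[Sequence[HeaderRule]] = None,
) -> APIResult:
    """End-to-end pipeline for a single patient."""
    lexicon = lexicon or Lexicon.default()
    mentions = extract_mentions(patient, lexicon, header_rules)
    eos = eosinophilia_events(patient.labs, config.eos_threshold_pct)
    family_asthma = [
        m
        for m in mentions
        if m.concept == "ASTHMA"
        and m.assertion is not None
        and m.assertion.experiencer == "family_parent"
        and m.assertion.polarity == "affirmed"
        and m.assertion.temporality == "current"
    ]
    note_texts = {n.note_id: n.text for n in patient.notes}
    parental = parental_asthma_events(patient.ppi, family_asthma, note_texts)
    timeline = criterion_timeline(patient, mentions, eos, parental, config)
    return classify_api(timeline, config, patient_id=patient.patient_id)


def classify_corpus(
    corpus: Sequence[PatientRecord],
    lexicon: Optional[Lexicon] = None,
    config: APIRuleConfig = APIRuleConfig(),
    header_rules: Optional[Sequence[HeaderRule]] = None,
) -> list[APIResult]:
    """Classify every patient; per-patient failures are reported in the
    result's ``error`` field and the remaining patients are processed.
    """
    lexicon = lexicon or Lexicon.default()
    results: list[APIResult] = []
    for patient in corpus:
        try:
            results.append(classify_patient(patient, lexicon, config, header_rules))
        except Exception as exc:  # pragma: no cover - defensive
            results.append(
                APIResult(
                    patient_id=patient.patient_id,
                    status="negative",
                    index_date=None,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return results


# ---------------------------------------------------------------------------
# Result I/O (JSON Lines)


def results_to_jsonl(results: Sequence[APIResult], path) -> None:
    import json
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        for r in results:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_results(path) -> list[APIResult]:
    import json
    from datetime import date as _date
    from pathlib import Path

    out: list[APIResult] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                APIResult(
                    patient_id=d["patient_id"],
                    status=d["status"],
                    index_date=(
                        _date.fromisoformat(d["index_date"])
                        if d.get("index_date")
                        else None
                    ),
                    criteria=[
                        CriterionEvidence(
                            c["criterion"],
                            (
                                _date.fromisoformat(c["satisfied_date"])
                                if c.get("satisfied_date")
                                else None
                            ),
                            tuple(c.get("support", ())),
                        )
                        for c in d.get("criteria", [])
                    ],
                    majors_met=d.get("majors_met", 0),
                    minors_met=d.get("minors_met", 0),
                    error=d.get("error"),
                )
            )
    return out
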