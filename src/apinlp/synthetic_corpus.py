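"""Seeded generator of synthetic pediatric EHR corpora with known
ground-truth API status.

Each patient gets a *plan*: wheeze episode dates, per-criterion evidence
dates, and distractors (negated mentions, sibling asthma, temperature-
sense "cold" contexts, hypothetical phrasing).  The plan is rendered into
sectioned note text from a fixed template bank, plus eosinophil labs and
questionnaire (PPI) records.  Gold labels are *entailed*: the generator
runs the API rule logic on its own plan, so the emitted label is provably
consistent with the generated documents, and a distractor-free corpus is
recovered perfectly by the extraction pipeline.

The default configuration emulates the kind of cohort the pipeline is
meant for: a few hundred children followed from birth for about seven
years, API prevalence near 8%, and risk-factor effect sizes in the range
reported for parental asthma history, eczema, allergic rhinitis and
maternal smoking.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from typing import Optional, Sequence, Union

import numpy as np

from .api_classifier import (
    APIResult,
    APIRuleConfig,
    CriterionEvidence,
    classify_api,
    frequent_wheeze_date,
)
from .corpus_model import (
    Analyte,
    ClinicalNote,
    GoldLabel,
    LabResult,
    PatientRecord,
    PPIField,
    PPIRecord,
    Race,
    Sex,
    YesNoUnknown,
)

__all__ = [
    "SynthConfig",
    "NoiseRates",
    "NotePlan",
    "PatientTruth",
    "GroundTruth",
    "COLD_SENSE_TEMPLATES",
    "generate_corpus",
    "inject_noise",
    "simulate_covariate_cohort",
]


# ---------------------------------------------------------------------------
# Template bank (shipped as code-level data so tests can extend it)

WHEEZE_SENTENCES = [
    "Audible wheezing noted on exam.",
    "Patient has been wheezing since last night.",
    "Expiratory wheeze heard bilaterally.",
    "He was wheezy overnight.",
    "Recurrent wheezing episode today.",
]

COLD_ILLNESS_SENTENCES = [
    "Symptoms began with a head cold.",
    "He is recovering from a cold this week.",
    "Ongoing URI symptoms.",
    "Diagnosed with an upper respiratory infection.",
]

COLD_TEMPERATURE_SENTENCES = [
    "Symptoms worsen with cold air exposure.",
    "He often feels cold in the mornings.",
    "A cold compress was applied.",
]

ECZEMA_SENTENCES = [
    "Eczema.",
    "Atopic dermatitis on flexural surfaces.",
    "Eczema, well controlled with emollients.",
]

AR_SENTENCES = [
    "Allergic rhinitis.",
    "Hay fever symptoms each spring.",
    "Seasonal allergies, managed with antihistamine.",
]

PARENT_ASTHMA_SENTENCES = [
    "Mother has asthma.",
    "Father was diagnosed with asthma in childhood.",
    "Mother carries a diagnosis of asthma.",
]

FILLER_SENTENCES = [
    "Well child visit today.",
    "Growth parameters within normal limits.",
    "Immunizations are up to date.",
    "Diet and sleep patterns reviewed.",
    "Anticipatory guidance provided.",
    "Physical exam otherwise unremarkable.",
    "Follow up as scheduled.",
]

NEGATED_DISTRACTOR_SENTENCES = [
    "No wheezing on exam.",
    "Lungs clear, no wheeze appreciated.",
    "Denies wheezing or cough.",
    "No eczema observed.",
]

HYPOTHETICAL_DISTRACTOR_SENTENCES = [
    "Return if wheezing recurs.",
    "Watch for wheezing with future illnesses.",
]

FAMILY_DISTRACTOR_SENTENCES = [
    "Older brother has asthma.",
    "Sister was treated for eczema as an infant.",
    "No family history of asthma.",
]

SAFE_IMPRESSIONS = ["Bronchiolitis.", "Acute bronchospasm.", "Viral illness."]

# Labeled sentence bank for the "cold" word-sense disambiguator.
COLD_SENSE_TEMPLATES: list[tuple[str, str]] = [
    ("He caught a cold last week.", "illness"),
    ("Symptoms began with a head cold.", "illness"),
    ("She is recovering from a common cold.", "illness"),
    ("Presents with a cold and cough.", "illness"),
    ("Diagnosed with an upper respiratory infection.", "illness"),
    ("Ongoing URI symptoms since Monday.", "illness"),
    ("Another cold this month.", "illness"),
    ("His cold started three days ago.", "illness"),
    ("Lingering cold symptoms.", "illness"),
    ("Mild nasopharyngitis noted.", "illness"),
    ("The cold resolved after a week.", "illness"),
    ("Frequent colds this winter.", "illness"),
    ("Cold symptoms with low grade fever.", "illness"),
    ("Had a bad cold during the holidays.", "illness"),
    ("Yet another head cold.", "illness"),
    ("Runny nose from a cold.", "illness"),
    ("Recurrent colds since daycare enrollment.", "illness"),
    ("Treated symptomatically for a cold.", "illness"),
    ("Recent upper respiratory infection.", "illness"),
    ("Brother also has a cold.", "illness"),
    ("The cold lasted ten days.", "illness"),
    ("Viral URI diagnosed today.", "illness"),
    ("Wheezing triggered by cold air.", "temperature_or_other"),
    ("Symptoms worsen with cold air exposure.", "temperature_or_other"),
    ("He feels cold at night.", "temperature_or_other"),
    ("She felt cold after swimming.", "temperature_or_other"),
    ("A cold compress was applied.", "temperature_or_other"),
    ("Use a cold pack for twenty minutes.", "temperature_or_other"),
    ("Reports cold intolerance.", "temperature_or_other"),
    ("Hands are cold to the touch.", "temperature_or_other"),
    ("Prefers cold drinks.", "temperature_or_other"),
    ("Cold water immersion advised.", "temperature_or_other"),
    ("Avoid cold weather exertion.", "temperature_or_other"),
    ("The room was cold during the exam.", "temperature_or_other"),
    ("Feet feel cold in the evening.", "temperature_or_other"),
    ("Gets cold easily in winter.", "temperature_or_other"),
    ("Cold milk seems to soothe his throat.", "temperature_or_other"),
    ("Symptoms flare in the cold season.", "temperature_or_other"),
    ("A cold shower helps the itching.", "temperature_or_other"),
    ("Exposure to cold temperatures worsens cough.", "temperature_or_other"),
    ("His fingers get cold and pale.", "temperature_or_other"),
    ("Felt cold and shivery overnight.", "temperature_or_other"),
]


# ---------------------------------------------------------------------------
# Configuration and ground-truth containers


@dataclass
class SynthConfig:
    """Generator configuration; the seed fixes the corpus byte-for-byte."""

    n_patients: int = 200
    seed: int = 7
    target_prevalence: float = 0.08
    # probability each criterion contributes evidence to a positive's plan
    criterion_probs: dict = dc_field(
        default_factory=lambda: {
            "parental_asthma": 0.45,
            "eczema": 0.45,
            "allergic_rhinitis": 0.30,
            "eosinophilia": 0.30,
            "wheeze_apart_from_cold": 0.60,
        }
    )
    negation_distractor_rate: float = 0.3
    family_distractor_rate: float = 0.2
    hypothetical_distractor_rate: float = 0.15
    cold_sense_temperature_share: float = 0.3
    ppi_share: float = 0.5  # parental evidence via PPI rather than note text
    mean_filler_notes: float = 2.0
    max_age_years: float = 7.0
    # risk factor -> (prevalence among negatives, odds multiplier for positives)
    covariate_effects: dict = dc_field(
        default_factory=lambda: {
            "family_history_asthma": (0.20, 5.8),
            "eczema_history": (0.22, 2.7),
            "allergic_rhinitis_history": (0.08, 3.4),
            "maternal_smoking": (0.06, 4.4),
        }
    )

    def __post_init__(self) -> None:
        probs = [
            self.target_prevalence,
            self.negation_distractor_rate,
            self.family_distractor_rate,
            self.hypothetical_distractor_rate,
            self.cold_sense_temperature_share,
            self.ppi_share,
            *self.criterion_probs.values(),
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.target_prevalence > 0:
            majors_ok = any(
                self.criterion_probs.get(k, 0) > 0
                for k in ("parental_asthma", "eczema")
            )
            minors_avail = sum(
                self.criterion_probs.get(k, 0) > 0
                for k in ("allergic_rhinitis", "eosinophilia", "wheeze_apart_from_cold")
            )
            if not majors_ok and minors_avail < 2:
                raise ValueError(
                    "infeasible config: positives requested but no satisfiable "
                    "major/minor evidence combination has positive probability"
                )

    def distractor_free(self) -> "SynthConfig":
        cfg = copy.deepcopy(self)
        cfg.negation_distractor_rate = 0.0
        cfg.family_distractor_rate = 0.0
        cfg.hypothetical_distractor_rate = 0.0
        return cfg


@dataclass
class NoiseRates:
    drop_ppi: float = 0.0
    cold_to_illness: float = 0.0  # corrupt cold-free wheeze notes with a URI
    wheeze_shift: float = 0.0  # push the last wheeze episode out of the window


@dataclass
class NotePlan:
    note_id: str
    date: date
    kind: str  # wheeze | eczema | ar | fh_asthma | filler | distractor
    with_illness_cold: bool = False
    with_temperature_cold: bool = False


@dataclass
class PatientTruth:
    patient_id: str
    status: str
    index_date: Optional[date]
    criterion_dates: dict  # criterion name -> ISO date or None
    note_plans: list[NotePlan] = dc_field(default_factory=list)
    distractors: list[str] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "status": self.status,
            "index_date": self.index_date.isoformat() if self.index_date else None,
            "criterion_dates": {
                k: (v.isoformat() if isinstance(v, date) else v)
                for k, v in self.criterion_dates.items()
            },
            "distractors": self.distractors,
        }


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth] = dc_field(default_factory=dict)

    def to_json(self, path) -> None:
        from pathlib import Path

        payload = {pid: t.to_dict() for pid, t in self.patients.items()}
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# Plan entailment (the generator's self-check and label source)


def _entail(
    wheeze_dates: Sequence[date],
    cold_free_wheeze_dates: Sequence[date],
    criterion_dates: dict,
    config: APIRuleConfig = APIRuleConfig(),
) -> APIResult:
    """Run the API rule on a plan's dates (no text involved)."""
    fw = frequent_wheeze_date(sorted(wheeze_dates), config)
    wafc = min(cold_free_wheeze_dates) if cold_free_wheeze_dates else None

    def ev(name: str, d: Optional[date]) -> CriterionEvidence:
        return CriterionEvidence(name, d, ("plan",) if d else ())

    timeline = [
        ev("FREQ_WHEEZE", fw),
        ev("MAJ_PARENT_ASTHMA", criterion_dates.get("parental_asthma")),
        ev("MAJ_ECZEMA", criterion_dates.get("eczema")),
        ev("MIN_ALLERGIC_RHINITIS", criterion_dates.get("allergic_rhinitis")),
        ev("MIN_WHEEZE_APART_FROM_COLD", wafc),
        ev("MIN_EOSINOPHILIA", criterion_dates.get("eosinophilia")),
    ]
    return classify_api(timeline, config)


# ---------------------------------------------------------------------------
# Rendering


def _pick(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _render_wheeze_note(
    rng: np.random.Generator,
    illness_cold: bool,
    temperature_cold: bool,
) -> str:
    hpi = [_pick(rng, WHEEZE_SENTENCES)]
    if illness_cold:
        hpi.append(_pick(rng, COLD_ILLNESS_SENTENCES))
    if temperature_cold:
        hpi.append(_pick(rng, COLD_TEMPERATURE_SENTENCES))
    hpi.append(_pick(rng, FILLER_SENTENCES))
    impression = (
        "Viral URI." if illness_cold else _pick(rng, SAFE_IMPRESSIONS)
    )
    return (
        "CHIEF COMPLAINT: Breathing difficulty.\n"
        f"HPI: {' '.join(hpi)}\n"
        f"IMPRESSION: {impression}"
    )


def _render_diagnosis_note(rng: np.random.Generator, sentences: Sequence[str]) -> str:
    return (
        f"HPI: {_pick(rng, FILLER_SENTENCES)}\n"
        f"IMPRESSION: {_pick(rng, sentences)}"
    )


def _render_family_history_note(rng: np.random.Generator, sentence: str) -> str:
    return (
        f"HPI: {_pick(rng, FILLER_SENTENCES)}\n"
        f"FAMILY HISTORY: {sentence}"
    )


def _render_filler_note(rng: np.random.Generator, extra: Optional[str] = None) -> str:
    body = [_pick(rng, FILLER_SENTENCES), _pick(rng, FILLER_SENTENCES)]
    if extra:
        body.append(extra)
    return "HPI: " + " ".join(body)


# ---------------------------------------------------------------------------
# Generation


def _sample_positive_plan(rng: np.random.Generator, cfg: SynthConfig, max_off: int):
    """Wheeze pair within the window plus a feasible evidence set."""
    d1 = int(rng.integers(120, max_off - 520))
    gap = int(rng.integers(20, 331))
    wheeze_offsets = [d1, d1 + gap]
    probs = cfg.criterion_probs
    chosen = {k: bool(rng.random() < probs.get(k, 0)) for k in probs}
    majors = chosen["parental_asthma"] or chosen["eczema"]
    minors = sum(
        chosen[k] for k in ("allergic_rhinitis", "eosinophilia", "wheeze_apart_from_cold")
    )
    if not majors and minors < 2:
        major_opts = [k for k in ("parental_asthma", "eczema") if probs.get(k, 0) > 0]
        if major_opts:
            chosen[_pick(rng, major_opts)] = True
        else:
            minor_opts = [
                k
                for k in ("allergic_rhinitis", "eosinophilia", "wheeze_apart_from_cold")
                if probs.get(k, 0) > 0 and not chosen[k]
            ]
            for k in minor_opts[: 2 - minors]:
                chosen[k] = True
    return wheeze_offsets, chosen


def _sample_negative_plan(rng: np.random.Generator, cfg: SynthConfig, max_off: int):
    """A plan that provably fails the API rule."""
    mode = _pick(rng, ["no_wheeze", "single_wheeze", "far_apart", "insufficient"])
    probs = cfg.criterion_probs
    if mode == "no_wheeze":
        wheeze_offsets: list[int] = []
        chosen = {k: bool(rng.random() < probs.get(k, 0)) for k in probs}
        chosen["wheeze_apart_from_cold"] = False
    elif mode == "single_wheeze":
        wheeze_offsets = [int(rng.integers(120, max_off - 40))]
        chosen = {k: bool(rng.random() < probs.get(k, 0)) for k in probs}
    elif mode == "far_apart":
        d1 = int(rng.integers(120, max_off - 560))
        gap = int(rng.integers(366, 521))
        wheeze_offsets = [d1, d1 + gap]
        chosen = {k: bool(rng.random() < probs.get(k, 0)) for k in probs}
    else:  # insufficient: frequent wheeze but no major and at most one minor
        d1 = int(rng.integers(120, max_off - 520))
        gap = int(rng.integers(20, 331))
        wheeze_offsets = [d1, d1 + gap]
        chosen = {k: False for k in probs}
        one_minor = _pick(rng, ["none", "allergic_rhinitis", "eosinophilia"])
        if one_minor != "none":
            chosen[one_minor] = True
        # every wheeze note carries an illness cold so the "apart from
        # colds" minor cannot fire
    return mode, wheeze_offsets, chosen


def generate_corpus(
    config: SynthConfig,
) -> tuple[list[PatientRecord], GroundTruth, list[GoldLabel]]:
    """Generate a corpus, its ground truth, and gold labels.

    Gold labels are the plan-entailed API status; the generator raises if
    a plan's entailed status contradicts the intended one (self-check).
    """
    rng = np.random.default_rng(config.seed)
    max_off = int(config.max_age_years * 365)
    corpus: list[PatientRecord] = []
    truth = GroundTruth()
    gold: list[GoldLabel] = []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        birth = date(2002, 1, 1) + timedelta(days=int(rng.integers(0, 5 * 365)))
        want_positive = bool(rng.random() < config.target_prevalence)

        if want_positive:
            wheeze_offsets, chosen = _sample_positive_plan(rng, config, max_off)
            mode = "positive"
        else:
            mode, wheeze_offsets, chosen = _sample_negative_plan(rng, config, max_off)

        wheeze_dates = [birth + timedelta(days=o) for o in wheeze_offsets]

        # evidence dates for non-wheeze criteria
        criterion_dates: dict[str, Optional[date]] = {}
        for name in ("parental_asthma", "eczema", "allergic_rhinitis", "eosinophilia"):
            if chosen.get(name):
                off = int(rng.integers(60, max_off - 30))
                criterion_dates[name] = birth + timedelta(days=off)
            else:
                criterion_dates[name] = None

        # which wheeze notes carry an illness-sense cold
        want_wafc = bool(chosen.get("wheeze_apart_from_cold")) and bool(wheeze_dates)
        illness_flags: list[bool] = []
        for j in range(len(wheeze_dates)):
            if mode == "insufficient":
                illness_flags.append(True)
            elif want_wafc:
                # at least the first episode is documented apart from a cold
                illness_flags.append(
                    False if j == 0 else bool(rng.random() < 0.5)
                )
            elif mode == "positive":
                illness_flags.append(True)
            else:
                illness_flags.append(bool(rng.random() < 0.5))
        cold_free = [d for d, ill in zip(wheeze_dates, illness_flags) if not ill]

        entailed = _entail(wheeze_dates, cold_free, criterion_dates)
        if want_positive and entailed.status != "positive":
            raise RuntimeError(f"self-check failed: planned positive {pid} entails negative")
        if not want_positive and entailed.status != "negative":
            raise RuntimeError(f"self-check failed: planned negative {pid} entails positive")

        # ---- render documents -------------------------------------------
        notes: list[ClinicalNote] = []
        labs: list[LabResult] = []
        ppi: list[PPIRecord] = []
        plans: list[NotePlan] = []
        distractors: list[str] = []
        nid = 0

        def add_note(text: str, d: date, kind: str, ill=False, temp=False) -> None:
            nonlocal nid
            note_id = f"{pid}-n{nid:03d}"
            nid += 1
            notes.append(ClinicalNote(note_id=note_id, date=d, text=text))
            plans.append(NotePlan(note_id, d, kind, ill, temp))

        for d, ill in zip(wheeze_dates, illness_flags):
            temp = (not ill) and bool(
                rng.random() < config.cold_sense_temperature_share
            )
            add_note(_render_wheeze_note(rng, ill, temp), d, "wheeze", ill, temp)

        if criterion_dates["eczema"]:
            add_note(
                _render_diagnosis_note(rng, ECZEMA_SENTENCES),
                criterion_dates["eczema"],
                "eczema",
            )
        if criterion_dates["allergic_rhinitis"]:
            add_note(
                _render_diagnosis_note(rng, AR_SENTENCES),
                criterion_dates["allergic_rhinitis"],
                "ar",
            )
        if criterion_dates["parental_asthma"]:
            d = criterion_dates["parental_asthma"]
            if rng.random() < config.ppi_share:
                fld = (
                    PPIField.mother_asthma
                    if rng.random() < 0.6
                    else PPIField.father_asthma
                )
                ppi.append(PPIRecord(date=d, field=fld, value=YesNoUnknown.yes))
            else:
                add_note(
                    _render_family_history_note(
                        rng, _pick(rng, PARENT_ASTHMA_SENTENCES)
                    ),
                    d,
                    "fh_asthma",
                )
        if criterion_dates["eosinophilia"]:
            labs.append(
                LabResult(
                    date=criterion_dates["eosinophilia"],
                    analyte=Analyte.eosinophil_pct,
                    value=round(float(rng.uniform(4.5, 12.0)), 1),
                    units="%",
                )
            )
        # a sub-threshold differential is ordinary background data
        if rng.random() < 0.4:
            labs.append(
                LabResult(
                    date=birth + timedelta(days=int(rng.integers(60, max_off - 30))),
                    analyte=Analyte.eosinophil_pct,
                    value=round(float(rng.uniform(0.3, 3.4)), 1),
                    units="%",
                )
            )

        # filler and distractor notes
        n_filler = int(rng.poisson(config.mean_filler_notes))
        for _ in range(n_filler):
            d = birth + timedelta(days=int(rng.integers(30, max_off)))
            add_note(_render_filler_note(rng), d, "filler")
        if rng.random() < config.negation_distractor_rate:
            d = birth + timedelta(days=int(rng.integers(30, max_off)))
            s = _pick(rng, NEGATED_DISTRACTOR_SENTENCES)
            add_note(_render_filler_note(rng, s), d, "distractor")
            distractors.append(f"negated:{s}")
        if rng.random() < config.hypothetical_distractor_rate:
            d = birth + timedelta(days=int(rng.integers(30, max_off)))
            s = _pick(rng, HYPOTHETICAL_DISTRACTOR_SENTENCES)
            add_note(_render_filler_note(rng, s), d, "distractor")
            distractors.append(f"hypothetical:{s}")
        if rng.random() < config.family_distractor_rate:
            d = birth + timedelta(days=int(rng.integers(30, max_off)))
            s = _pick(rng, FAMILY_DISTRACTOR_SENTENCES)
            add_note(_render_family_history_note(rng, s), d, "distractor")
            distractors.append(f"family:{s}")

        # ---- demographics and covariates ---------------------------------
        sex = Sex.male if rng.random() < 0.48 else Sex.female
        race = Race.white if rng.random() < 0.74 else Race.nonwhite
        late_preterm = bool(rng.random() < 0.46)
        ga = (
            round(float(rng.uniform(34.0, 36.9)), 1)
            if late_preterm
            else round(float(rng.uniform(37.0, 41.0)), 1)
        )
        covariates: dict[str, Union[float, int, bool, None]] = {}
        positive = entailed.status == "positive"
        for name, (p0, or_mult) in config.covariate_effects.items():
            odds0 = p0 / (1 - p0)
            p1 = (odds0 * or_mult) / (1 + odds0 * or_mult)
            p = p1 if positive else p0
            covariates[name] = int(rng.random() < p)

        corpus.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                race=race,
                gestational_age_weeks=ga,
                birth_date=birth,
                notes=sorted(notes, key=lambda n: (n.date, n.note_id)),
                labs=sorted(labs, key=lambda l: l.date),
                ppi=ppi,
                covariates=covariates,
            )
        )
        truth.patients[pid] = PatientTruth(
            patient_id=pid,
            status=entailed.status,
            index_date=entailed.index_date,
            criterion_dates={
                **{k: v for k, v in criterion_dates.items()},
                "wheeze_episodes": [d.isoformat() for d in wheeze_dates],
                "wheeze_apart_from_cold": min(cold_free) if cold_free else None,
            },
            note_plans=plans,
            distractors=distractors,
        )
        gold.append(
            GoldLabel(
                patient_id=pid,
                status=entailed.status,
                index_date=entailed.index_date,
            )
        )
    return corpus, truth, gold


# ---------------------------------------------------------------------------
# Controlled corruption


def inject_noise(
    corpus: Sequence[PatientRecord],
    truth: GroundTruth,
    rates: NoiseRates,
    seed: int,
) -> tuple[list[PatientRecord], list[dict]]:
    """Apply controlled corruptions and return (new corpus, corruption log).

    The random draws are made for every corruption candidate regardless of
    the rates, so raising a rate with the same seed corrupts a superset of
    patients (nested corruption sets; monotone sweeps are meaningful).
    """
    rng = np.random.default_rng(seed)
    out: list[PatientRecord] = []
    log: list[dict] = []
    for rec in sorted(corpus, key=lambda r: r.patient_id):
        rec = rec.model_copy(deep=True)
        t = truth.patients.get(rec.patient_id)

        u = rng.random()
        if u < rates.drop_ppi and rec.ppi:
            log.append({"patient_id": rec.patient_id, "action": "drop_ppi"})
            rec.ppi = []

        if t is not None:
            wheeze_plans = [p for p in t.note_plans if p.kind == "wheeze"]
            for plan in wheeze_plans:
                u = rng.random()
                if plan.with_illness_cold:
                    continue
                if u < rates.cold_to_illness:
                    for note in rec.notes:
                        if note.note_id == plan.note_id:
                            note.text += "\nOngoing URI symptoms."
                            log.append(
                                {
                                    "patient_id": rec.patient_id,
                                    "action": "cold_to_illness",
                                    "note_id": note.note_id,
                                }
                            )
            u = rng.random()
            if u < rates.wheeze_shift and len(wheeze_plans) >= 2:
                first = min(p.date for p in wheeze_plans)
                last_plan = max(wheeze_plans, key=lambda p: p.date)
                new_date = first + timedelta(days=366)
                for note in rec.notes:
                    if note.note_id == last_plan.note_id:
                        note.date = new_date
                rec.notes.sort(key=lambda n: (n.date, n.note_id))
                log.append(
                    {
                        "patient_id": rec.patient_id,
                        "action": "wheeze_shift",
                        "note_id": last_plan.note_id,
                        "new_date": new_date.isoformat(),
                    }
                )
        out.append(rec)
    return out, log


# ---------------------------------------------------------------------------
# Lightweight covariate-effect simulation (no text rendering)


def simulate_covariate_cohort(
    n: int,
    exposure_prev: float,
    true_or: float,
    baseline_outcome_prob: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (outcome, covariate) pairs with an exact planted odds ratio.

    Covariate ~ Bernoulli(exposure_prev); the outcome follows a logistic
    model with intercept logit(baseline_outcome_prob) and slope ln(true_or),
    so the conditional odds ratio equals ``true_or`` by construction.
    """
    if not (0 < exposure_prev < 1 and 0 < baseline_outcome_prob < 1):
        raise ValueError("probabilities must be in (0, 1)")
    x = (rng.random(n) < exposure_prev).astype(int)
    alpha = np.log(baseline_outcome_prob / (1 - baseline_outcome_prob))
    logit = alpha + np.log(true_or) * x
    p = 1.0 / (1.0 + np.exp(-logit))
    y = (rng.random(n) < p).astype(int)
    return y, x
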