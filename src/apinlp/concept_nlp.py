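"""Text processing: find API concept mentions in sectioned notes and
assign assertion status (polarity, temporality, experiencer).

The extraction is entirely rule-based and deterministic: literal phrase
patterns matched whole-word and case-insensitively, NegEx-style negation
with a forward token-scope window, and experiencer attribution driven by
relative terms and the family-history section.  The word "cold" gets a
dedicated sense classifier because clinical text uses it both for the
common cold (an illness, relevant to the "wheezing apart from colds"
criterion) and for temperature/sensation contexts such as "cold air".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .corpus_model import ClinicalNote, PatientRecord
from .sectioner import HeaderRule, NoteSection, default_header_rules, segment

__all__ = [
    "CONCEPTS",
    "Lexicon",
    "AssertionStatus",
    "ConceptMention",
    "split_sentences",
    "match_concepts",
    "detect_assertion",
    "classify_cold_sense",
    "extract_mentions",
]

CONCEPTS = ("WHEEZE", "COLD", "ECZEMA", "ALLERGIC_RHINITIS", "ASTHMA")

_WORD_RE = re.compile(r"[A-Za-z0-9/']+")

# sentence boundary guard: tokens whose trailing period is not a full stop
_ABBREVIATIONS = frozenset(
    "dr mr mrs ms jr sr vs etc approx dept appt wk wks yr yrs mos".split()
) | {"e.g", "i.e"}


def _phrase_regex(phrase: str) -> re.Pattern:
    """Whole-word, case-insensitive, whitespace-tolerant literal matcher."""
    body = r"[ \t]+".join(re.escape(tok) for tok in phrase.split())
    return re.compile(
        r"(?<![A-Za-z0-9])" + body + r"(?![A-Za-z0-9])", re.IGNORECASE
    )


@dataclass
class Lexicon:
    """Concept surface patterns, section constraints, and assertion triggers."""

    patterns: dict[str, list[str]]
    sections: dict[str, Optional[list[str]]]
    negation_triggers: list[str]
    hypothetical_triggers: list[str]
    parent_terms: list[str]
    other_relative_terms: list[str]
    scope_terminators: list[str] = field(
        default_factory=lambda: ["but", "however", "although", "though", "except"]
    )
    scope_window_tokens: int = 6
    # lenient default: an unattributed mention inside the family-history
    # section counts as parental; strict mode demands a named parent term
    strict_parent_attribution: bool = False

    def __post_init__(self) -> None:
        for concept in CONCEPTS:
            if not self.patterns.get(concept):
                raise ValueError(f"concept {concept} has no surface patterns")
        concept_surface = {
            p.lower() for pats in self.patterns.values() for p in pats
        }
        for name, triggers in (
            ("negation", self.negation_triggers),
            ("hypothetical", self.hypothetical_triggers),
        ):
            clash = concept_surface & {t.lower() for t in triggers}
            if clash:
                raise ValueError(f"{name} triggers overlap concept patterns: {clash}")
        self._concept_rx = {
            concept: [_phrase_regex(p) for p in pats]
            for concept, pats in self.patterns.items()
        }
        self._neg_rx = [_phrase_regex(t) for t in self.negation_triggers]
        self._hyp_rx = [_phrase_regex(t) for t in self.hypothetical_triggers]
        self._parent_rx = [_phrase_regex(t) for t in self.parent_terms]
        self._other_rel_rx = [_phrase_regex(t) for t in self.other_relative_terms]
        self._term_rx = [_phrase_regex(t) for t in self.scope_terminators]

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "Lexicon":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        concepts = data["concepts"]
        kwargs = dict(
            patterns={c: list(v["patterns"]) for c, v in concepts.items()},
            sections={c: v.get("sections") for c, v in concepts.items()},
            negation_triggers=list(data["negation_triggers"]),
            hypothetical_triggers=list(data["hypothetical_triggers"]),
            parent_terms=list(data["parent_terms"]),
            other_relative_terms=list(data["other_relative_terms"]),
            scope_terminators=list(data.get("scope_terminators", [])),
            scope_window_tokens=int(data.get("scope_window_tokens", 6)),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def default(cls, **overrides) -> "Lexicon":
        with resources.as_file(
            resources.files("apinlp.data").joinpath("lexicon.yaml")
        ) as p:
            return cls.from_yaml(p, **overrides)


@dataclass(frozen=True)
class AssertionStatus:
    polarity: str  # affirmed | negated
    temporality: str  # current | hypothetical
    experiencer: str  # patient | family_parent | family_other

    @property
    def is_affirmed_current_patient(self) -> bool:
        return (
            self.polarity == "affirmed"
            and self.temporality == "current"
            and self.experiencer == "patient"
        )


@dataclass(frozen=True)
class ConceptMention:
    """A located concept hit; all offsets are into the raw note text."""

    concept: str
    note_id: str
    date: object  # datetime.date (kept loose for serialization)
    start: int
    end: int
    text: str
    sentence_start: int
    sentence_end: int
    section_type: str
    assertion: Optional[AssertionStatus] = None
    sense: str = "illness"  # COLD only; every other concept stays "illness"

    def to_dict(self) -> dict:
        d = {
            "concept": self.concept,
            "note_id": self.note_id,
            "date": self.date.isoformat(),
            "start": self.start,
            "end": self.end,
            "text": self.text,
            "sentence_start": self.sentence_start,
            "sentence_end": self.sentence_end,
            "section_type": self.section_type,
            "sense": self.sense,
        }
        if self.assertion is not None:
            d.update(
                polarity=self.assertion.polarity,
                temporality=self.assertion.temporality,
                experiencer=self.assertion.experiencer,
            )
        return d


# ---------------------------------------------------------------------------
# Sentence splitting


def _is_abbreviation_period(text: str, i: int) -> bool:
    m = re.search(r"[A-Za-z][A-Za-z.]*$", text[:i])
    if m is None:
        return False
    return m.group().lower() in _ABBREVIATIONS


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans that tile it exactly.

    Boundaries are ``. ! ?`` and newlines; a period preceded by a known
    abbreviation or flanked by digits (a decimal) does not split.
    Trailing punctuation runs and whitespace attach to the finished
    sentence so concatenating the spans reproduces the text.
    """
    n = len(text)
    if n == 0:
        return []
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    while i < n:
        c = text[i]
        boundary = False
        if c == "\n":
            boundary = True
        elif c in "!?":
            boundary = True
        elif c == ".":
            decimal = (
                0 < i < n - 1 and text[i - 1].isdigit() and text[i + 1].isdigit()
            )
            boundary = not decimal and not _is_abbreviation_period(text, i)
        if boundary:
            j = i + 1
            while j < n and text[j] in ".!?)\"'":
                j += 1
            while j < n and text[j] in " \t\n":
                j += 1
            spans.append((start, j))
            start = j
            i = j
        else:
            i += 1
    if start < n:
        spans.append((start, n))
    return spans


# ---------------------------------------------------------------------------
# Concept matching


def match_concepts(
    sections: Sequence[NoteSection],
    lexicon: Lexicon,
    note: ClinicalNote,
) -> list[ConceptMention]:
    """Find every pattern occurrence in its allowed sections.

    Matches are whole-word and case-insensitive; overlapping matches for
    the same concept are merged to the longest span.  Assertion status is
    not yet set.
    """
    raw: dict[str, list[tuple[int, int]]] = {c: [] for c in CONCEPTS}
    for sec in sections:
        for concept in CONCEPTS:
            allowed = lexicon.sections.get(concept)
            if allowed is not None and sec.section_type not in allowed:
                continue
            for rx in lexicon._concept_rx[concept]:
                for m in rx.finditer(sec.text):
                    raw[concept].append((sec.start + m.start(), sec.start + m.end()))

    sections_sorted = sorted(sections, key=lambda s: s.start)

    def sect_type(offset: int) -> str:
        for sec in sections_sorted:
            if sec.start <= offset < sec.end:
                return sec.section_type
        return sections_sorted[-1].section_type if sections_sorted else "other"

    mentions: list[ConceptMention] = []
    for concept, spans in raw.items():
        # longest-first keep, drop anything overlapping an accepted span
        kept: list[tuple[int, int]] = []
        for s, e in sorted(spans, key=lambda se: (-(se[1] - se[0]), se[0])):
            if all(e <= ks or s >= ke for ks, ke in kept):
                kept.append((s, e))
        for s, e in sorted(kept):
            sec_type = sect_type(s)
            sec = next(x for x in sections_sorted if x.start <= s < x.end)
            sent_spans = split_sentences(sec.text)
            local = s - sec.start
            sent = next(
                (ss for ss in sent_spans if ss[0] <= local < ss[1]),
                (0, len(sec.text)),
            )
            mentions.append(
                ConceptMention(
                    concept=concept,
                    note_id=note.note_id,
                    date=note.date,
                    start=s,
                    end=e,
                    text=note.text[s:e],
                    sentence_start=sec.start + sent[0],
                    sentence_end=sec.start + sent[1],
                    section_type=sec_type,
                )
            )
    mentions.sort(key=lambda m: (m.start, m.concept))
    return mentions


# ---------------------------------------------------------------------------
# Assertion


def _tokens_between(text: str) -> int:
    return len(_WORD_RE.findall(text))


def _scope_reaches(
    sentence: str, trigger_end: int, mention_rel_start: int, lexicon: Lexicon
) -> bool:
    between = sentence[trigger_end:mention_rel_start]
    if _tokens_between(between) > lexicon.scope_window_tokens:
        return False
    if ";" in between or ":" in between:
        return False
    return not any(rx.search(between) for rx in lexicon._term_rx)


def _triggered(
    sentence: str, mention_rel_start: int, trigger_rx: list[re.Pattern], lexicon: Lexicon
) -> bool:
    for rx in trigger_rx:
        for m in rx.finditer(sentence):
            if m.end() <= mention_rel_start and _scope_reaches(
                sentence, m.end(), mention_rel_start, lexicon
            ):
                return True
    return False


def detect_assertion(
    mention: ConceptMention,
    sentence_text: str,
    lexicon: Lexicon,
) -> AssertionStatus:
    """Assign polarity, temporality, and experiencer for one mention.

    Negation: a negation trigger preceding the mention in the same
    sentence, within the forward scope window, with no scope-terminating
    conjunction in between.  Hypothetical triggers use the same scoping.
    Experiencer: a parent term anywhere in the sentence wins; then other
    relatives; then the family-history section (parental when lenient,
    other-relative when strict); otherwise the patient.
    """
    rel = mention.start - mention.sentence_start
    negated = _triggered(sentence_text, rel, lexicon._neg_rx, lexicon)
    hypothetical = _triggered(sentence_text, rel, lexicon._hyp_rx, lexicon)

    if any(rx.search(sentence_text) for rx in lexicon._parent_rx):
        experiencer = "family_parent"
    elif any(rx.search(sentence_text) for rx in lexicon._other_rel_rx):
        experiencer = "family_other"
    elif mention.section_type == "family_history":
        experiencer = (
            "family_other" if lexicon.strict_parent_attribution else "family_parent"
        )
    else:
        experiencer = "patient"

    return AssertionStatus(
        polarity="negated" if negated else "affirmed",
        temporality="hypothetical" if hypothetical else "current",
        experiencer=experiencer,
    )


# ---------------------------------------------------------------------------
# "cold" word-sense disambiguation

_TEMP_NEXT = frozenset(
    """air water weather compress compresses pack packs intolerance exposure
    temperature temperatures extremities hands feet fingers toes drink drinks
    beverages milk season shower bath room environment to""".split()
)
_FEEL_PREV = frozenset(
    "feels feel felt feeling gets got getting is was very quite bit runs run".split()
)


def classify_cold_sense(mention: ConceptMention, sentence_text: str) -> str:
    """Decide whether a COLD hit means the illness or a temperature context.

    Multiword and plural surface forms ("common cold", "head cold", "URI",
    "colds") are always the illness; a bare "cold" is temperature/sensation
    when followed by an enumerated temperature noun ("cold air", "cold
    compress") or preceded by a sensation verb ("feels cold"), and the
    illness otherwise ("a cold", "caught cold last week").
    """
    if mention.concept != "COLD":
        raise ValueError("classify_cold_sense applies only to COLD mentions")
    surface = mention.text.lower()
    if surface != "cold":
        return "illness"
    rel_start = mention.start - mention.sentence_start
    rel_end = mention.end - mention.sentence_start
    after = sentence_text[rel_end:]
    before = sentence_text[:rel_start]
    next_m = _WORD_RE.search(after)
    next_tok = next_m.group().lower() if next_m else ""
    prev_toks = _WORD_RE.findall(before)
    prev_tok = prev_toks[-1].lower() if prev_toks else ""
    if next_tok in _TEMP_NEXT:
        return "temperature_or_other"
    if prev_tok in _FEEL_PREV:
        return "temperature_or_other"
    return "illness"


# ---------------------------------------------------------------------------
# Full extraction


def extract_mentions(
    patient: PatientRecord,
    lexicon: Optional[Lexicon] = None,
    header_rules: Optional[Sequence[HeaderRule]] = None,
) -> list[ConceptMention]:
    """Run segment → sentence split → match → assertion → cold sense
    over every note of a patient.  Deterministic; mentions carry note dates.
    """
    lexicon = lexicon or Lexicon.default()
    rules = header_rules if header_rules is not None else default_header_rules()
    out: list[ConceptMention] = []
    for note in patient.notes:
        sections = segment(note, rules)
        for mention in match_concepts(sections, lexicon, note):
            sentence = note.text[mention.sentence_start : mention.sentence_end]
            assertion = detect_assertion(mention, sentence, lexicon)
            sense = (
                classify_cold_sense(mention, sentence)
                if mention.concept == "COLD"
                else "illness"
            )
            out.append(replace(mention, assertion=assertion, sense=sense))
    return out
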