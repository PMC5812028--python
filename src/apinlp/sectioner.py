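"""Split clinical notes into typed sections by matching header lines.

Concept rules downstream apply section constraints (e.g. parental-asthma
evidence is only taken from the family-history section), so segmentation
must be deterministic and must tile the note: the section spans are
non-overlapping, ordered, and their union is exactly the note text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .corpus_model import ClinicalNote

__all__ = [
    "SECTION_TYPES",
    "HeaderRule",
    "NoteSection",
    "load_header_rules",
    "default_header_rules",
    "segment",
    "section_of",
]

SECTION_TYPES = (
    "family_history",
    "diagnosis_impression",
    "chief_complaint",
    "hpi",
    "allergies",
    "social_history",
    "medications",
    "other",
)


@dataclass(frozen=True)
class HeaderRule:
    """A header phrase that opens a section of the given type."""

    pattern: str
    section_type: str
    regex: re.Pattern = None  # compiled on construction

    def __post_init__(self):
        if self.section_type not in SECTION_TYPES:
            raise ValueError(f"unknown section type {self.section_type!r}")
        # header must start the line and be followed by ':' or end-of-line
        rx = re.compile(
            r"^[ \t]*(" + re.escape(self.pattern) + r")[ \t]*(?::|$)",
            re.IGNORECASE | re.MULTILINE,
        )
        object.__setattr__(self, "regex", rx)


@dataclass(frozen=True)
class NoteSection:
    """A typed span of a note; offsets are 0-based half-open into the note text."""

    section_type: str
    start: int
    end: int
    text: str


def load_header_rules(path: Union[str, Path]) -> list[HeaderRule]:
    """Load header rules from a tab-separated config (pattern<TAB>section_type)."""
    rules: list[HeaderRule] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        pattern, section_type = line.split("\t")
        rules.append(HeaderRule(pattern.strip(), section_type.strip()))
    if not rules:
        raise ValueError(f"no header rules found in {path}")
    return rules


_DEFAULT_RULES: Optional[list[HeaderRule]] = None


def default_header_rules() -> list[HeaderRule]:
    """The shipped header lexicon (editable copy in the package data dir)."""
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        with resources.as_file(
            resources.files("apinlp.data").joinpath("section_headers.tsv")
        ) as p:
            _DEFAULT_RULES = load_header_rules(p)
    return _DEFAULT_RULES


def _header_at_line(
    text: str, line_start: int, rules: Sequence[HeaderRule]
) -> Optional[tuple[int, str]]:
    """If a header rule matches at this line start, return (header_len, type).

    Ties between rules matching the same line: longest matched header wins,
    then rule order (both deterministic).
    """
    best: Optional[tuple[int, int, str]] = None  # (-len, rule_idx, type)
    for idx, rule in enumerate(rules):
        m = rule.regex.match(text, line_start)
        if m:
            cand = (-len(m.group(1)), idx, rule.section_type)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    return -best[0], best[2]


def segment(
    note: Union[ClinicalNote, str],
    header_rules: Optional[Sequence[HeaderRule]] = None,
) -> list[NoteSection]:
    """Segment a note into typed sections.

    Text before the first recognized header is ``other``; each recognized
    header opens a section running to the next header or the end of the
    note (the header line belongs to its own section).  A note with no
    headers yields a single ``other`` section spanning the whole text.
    """
    text = note.text if isinstance(note, ClinicalNote) else note
    rules = list(header_rules) if header_rules is not None else default_header_rules()
    if not rules:
        raise ValueError("header_rules must be non-empty")
    if text == "":
        return []

    # line start offsets
    starts = [0] + [m.end() for m in re.finditer(r"\n", text) if m.end() < len(text)]
    boundaries: list[tuple[int, str]] = []  # (offset, section_type)
    for ls in starts:
        hit = _header_at_line(text, ls, rules)
        if hit is not None:
            boundaries.append((ls, hit[1]))

    sections: list[NoteSection] = []
    if not boundaries or boundaries[0][0] > 0:
        end = boundaries[0][0] if boundaries else len(text)
        sections.append(NoteSection("other", 0, end, text[0:end]))
    for i, (off, stype) in enumerate(boundaries):
        end = boundaries[i + 1][0] if i + 1 < len(boundaries) else len(text)
        sections.append(NoteSection(stype, off, end, text[off:end]))
    return sections


def section_of(offset: int, sections: Sequence[NoteSection]) -> str:
    """Return the type of the unique section containing ``offset``."""
    for sec in sections:
        if sec.start <= offset < sec.end:
            return sec.section_type
    raise IndexError(f"offset {offset} outside the segmented note")
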