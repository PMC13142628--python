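"""Keyword-based pre-filtering.

A :class:`~phenonote.config.KeywordSpec` is compiled into one unified
case-insensitive alternation; every sentence of a note that hits the
pattern spawns a candidate segment consisting of the matching sentence plus
its immediately preceding and succeeding sentences (clipped at the note's
boundaries).  Overlapping or adjacent candidate spans within a note are
merged; each merged segment later casts one vote, so a note with several
well-separated mentions contributes several votes.

Units (subjects / visits) whose notes yield no segment at all are put in
the NNF ("no notes found") set and never reach the classifier.
"""

from __future__ import annotations

import datetime
import re
from collections.abc import Callable, Iterable, Mapping

from .config import KeywordSpec
from .records import ClinicalNote, Segment
from .sentences import split_sentences


class PatternError(ValueError):
    """A keyword entry failed to compile, named in the message."""


def compile_pattern(spec: KeywordSpec) -> re.Pattern:
    """Compile ``spec`` into a single case-insensitive alternation.

    Literal synonyms are regex-escaped and anchored in word boundaries;
    flexible patterns are taken verbatim.  Each flexible pattern is
    compiled on its own first so a failure names the offending entry.
    """
    parts: list[str] = []
    for syn in spec.literal_synonyms:
        if not syn.strip():
            raise PatternError("empty literal synonym in keyword spec")
        parts.append(rf"\b{re.escape(syn)}\b")
    for pat in spec.flexible_patterns:
        try:
            re.compile(pat, re.IGNORECASE)
        except re.error as exc:
            raise PatternError(f"flexible pattern {pat!r} does not compile: {exc}") from exc
        parts.append(f"(?:{pat})")
    return re.compile("|".join(parts), re.IGNORECASE)


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent inclusive index intervals."""
    merged: list[tuple[int, int]] = []
    for a, b in sorted(spans):
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def extract_segments(
    note: ClinicalNote,
    matcher: re.Pattern,
    splitter: Callable[[str], list[str]] = split_sentences,
) -> list[Segment]:
    """Extract keyword segments from one note.

    Each keyword-bearing sentence i yields the candidate span
    [i-1, i+1] clipped to the note; overlapping/adjacent candidates are
    merged into one segment whose text is the spanned sentences joined
    with spaces and whose ``match_info`` lists the matched keyword strings.
    """
    sentences = splitter(note.text)
    if not sentences:
        return []
    hits = [i for i, s in enumerate(sentences) if matcher.search(s)]
    if not hits:
        return []
    n = len(sentences)
    spans = merge_spans((max(i - 1, 0), min(i + 1, n - 1)) for i in hits)
    segments = []
    for a, b in spans:
        text = " ".join(sentences[a : b + 1])
        matched = tuple(m.group(0) for m in matcher.finditer(text))
        segments.append(
            Segment(
                note_id=note.note_id,
                sentence_span=(a, b),
                text=text,
                source_method="regex",
                match_info=matched,
            )
        )
    return segments


def filter_cohort_regex(
    notes_by_unit: Mapping[str, list[ClinicalNote]],
    matcher: re.Pattern,
) -> tuple[dict[str, list[Segment]], set[str]]:
    """Run keyword extraction over every unit's notes.

    Returns (segments per unit, NNF unit set); a unit lands in exactly one
    of the two.  Note order within a unit does not affect the result:
    notes are processed in (note_date, note_id) order.
    """
    segments_by_unit: dict[str, list[Segment]] = {}
    nnf: set[str] = set()
    for unit, notes in notes_by_unit.items():
        segs: list[Segment] = []
        for note in sorted(notes, key=lambda n: (n.note_date or datetime.date.min, n.note_id)):
            segs.extend(extract_segments(note, matcher))
        if segs:
            segments_by_unit[unit] = segs
        else:
            nnf.add(unit)
    return segments_by_unit, nnf
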