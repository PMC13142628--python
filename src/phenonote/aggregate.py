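"""Majority-vote aggregation of segment labels to unit annotations.

A unit is a subject (whole history), an explicit visit (admission id), or
a date window around an anchor event.  Unknown labels are excluded before
counting; more Yes than No votes gives YES, more No gives NO, a tie — or
nothing but Unknowns — gives UNDECIDED, and a unit with no segments at all
is NNF.  Keyword-filtered units cast one vote per segment (so one note can
cast several); retrieval-filtered units cast one vote per note.
"""

from __future__ import annotations

import datetime
from collections import Counter
from collections.abc import Callable, Iterable, Mapping, Sequence

from .records import ClinicalNote, FinalLabel, ICDEvent, Segment, SegmentLabel, UnitAnnotation


class PipelineError(RuntimeError):
    """Internal inconsistency between pipeline stages."""


def select_notes_in_window(
    notes: Iterable[ClinicalNote],
    anchor: datetime.date,
    window_days: int,
) -> list[ClinicalNote]:
    """Notes dated within the n-day window centred on ``anchor``.

    The half-window is floor(n/2) days and both endpoints are inclusive:
    a note qualifies iff |note_date - anchor| <= floor(window_days/2).
    Undated notes never qualify.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    half = window_days // 2
    return [
        n for n in notes
        if n.note_date is not None and abs((n.note_date - anchor).days) <= half
    ]


def majority_vote(labels: Sequence[SegmentLabel]) -> FinalLabel:
    """Majority vote over segment labels, Unknowns excluded.

    YES if strictly more YES than NO votes, NO if the reverse, UNDECIDED
    on a tie or when every label is UNKNOWN.  Empty input is a pipeline
    error — a unit with no labels is NNF upstream, not a vote.
    """
    if not labels:
        raise ValueError("majority_vote requires at least one label (empty unit is NNF)")
    counts = Counter(labels)
    n_yes, n_no = counts[SegmentLabel.YES], counts[SegmentLabel.NO]
    if n_yes > n_no:
        return FinalLabel.YES
    if n_no > n_yes:
        return FinalLabel.NO
    return FinalLabel.UNDECIDED


def _vote_labels(
    labeled: Sequence[tuple[Segment, SegmentLabel]],
    method: str,
) -> list[SegmentLabel]:
    if method == "regex" or method == "baseline":
        return [label for _, label in labeled]
    if method == "rag":
        # one vote per note, guaranteed by construction upstream
        seen: dict[str, SegmentLabel] = {}
        for seg, label in labeled:
            if seg.note_id in seen:
                raise PipelineError(
                    f"note {seg.note_id!r} carries more than one retrieval segment"
                )
            seen[seg.note_id] = label
        return list(seen.values())
    raise ValueError(f"unknown method {method!r}")


def annotate_units(
    labeled_by_unit: Mapping[str, Sequence[tuple[Segment, SegmentLabel]]],
    method: str,
    nnf_units: Iterable[str],
    level: str = "subject",
) -> list[UnitAnnotation]:
    """Aggregate labeled segments into one annotation per unit.

    NNF units are emitted with zero counts and final label NNF.  A unit
    appearing both in the NNF set and in the segment map is a pipeline
    inconsistency and raises.
    """
    nnf_set = set(nnf_units)
    overlap = nnf_set & set(labeled_by_unit)
    if overlap:
        raise PipelineError(f"units both NNF and segmented: {sorted(overlap)}")
    annotations = []
    for unit, labeled in labeled_by_unit.items():
        votes = _vote_labels(labeled, method)
        counts = Counter(votes)
        annotations.append(
            UnitAnnotation(
                unit_id=unit,
                level=level,
                final_label=majority_vote(votes),
                n_yes=counts[SegmentLabel.YES],
                n_no=counts[SegmentLabel.NO],
                n_unknown=counts[SegmentLabel.UNKNOWN],
            )
        )
    for unit in sorted(nnf_set):
        annotations.append(UnitAnnotation(unit_id=unit, level=level, final_label=FinalLabel.NNF))
    return annotations


def annotate_events(
    notes_by_subject: Mapping[str, Sequence[ClinicalNote]],
    events: Iterable[ICDEvent],
    window_days: int,
    annotate_window: Callable[[list[ClinicalNote], str], UnitAnnotation],
) -> dict[tuple[str, int], UnitAnnotation]:
    """One windowed annotation per dated diagnosis event.

    For the j-th event of subject i, the notes within the window centred
    on the event date are annotated independently (a note shared by two
    overlapping windows votes in both).  Keys are (subject_id, j) with j
    numbering that subject's events in date order from 0.  An undated
    event raises.
    """
    out: dict[tuple[str, int], UnitAnnotation] = {}
    by_subject: dict[str, list[ICDEvent]] = {}
    for ev in events:
        if ev.event_date is None:
            raise ValueError(
                f"event {ev.code!r} of subject {ev.subject_id!r} lacks a date "
                "(required for time-window annotation)"
            )
        by_subject.setdefault(ev.subject_id, []).append(ev)
    for subject_id, evs in by_subject.items():
        notes = list(notes_by_subject.get(subject_id, []))
        for j, ev in enumerate(sorted(evs, key=lambda e: (e.event_date, e.code))):
            unit_id = f"{subject_id}@{ev.event_date.isoformat()}"
            selected = select_notes_in_window(notes, ev.event_date, window_days)
            out[(subject_id, j)] = annotate_window(selected, unit_id)
    return out
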