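"""Core domain records.

The pipeline moves data through four shapes: a :class:`ClinicalNote` (one
timestamped free-text record attributed to a subject), an :class:`ICDEvent`
(one reference-standard diagnosis code, optionally dated), a
:class:`Segment` (the short run of sentences a pre-filter selected from a
note), and a :class:`UnitAnnotation` (the aggregated result for one
evaluation unit — a subject, an admission, or a date window).

Segment-level classification is three-valued (:class:`SegmentLabel`:
YES / NO / UNKNOWN); aggregated unit results are four-valued
(:class:`FinalLabel`: YES / NO / UNDECIDED / NNF, where NNF means the
pre-filter found no relevant text at all for the unit).
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field


class SegmentLabel(enum.Enum):
    """Three-valued classification of a single text segment."""

    YES = "Yes"
    NO = "No"
    UNKNOWN = "Unknown"


class FinalLabel(enum.Enum):
    """Four-valued aggregated annotation for an evaluation unit."""

    YES = "Yes"
    NO = "No"
    UNDECIDED = "Undecided"
    NNF = "NNF"


@dataclass(frozen=True)
class ClinicalNote:
    """One free-text clinical note.

    ``note_date`` may be None only when no visit-level or time-window
    analysis is requested; readers enforce uniqueness of ``note_id``.
    Empty ``text`` is legal and yields zero segments downstream.
    """

    note_id: str
    subject_id: str
    text: str
    note_date: datetime.date | None = None
    visit_id: str | None = None


@dataclass(frozen=True)
class ICDEvent:
    """One reference-standard diagnosis event.

    ``event_date`` is required for time-sensitive (per-event window)
    evaluation; a subject may carry several dated events of the same code,
    each treated as a distinct ground-truth event.
    """

    subject_id: str
    code: str
    event_date: datetime.date | None = None


@dataclass(frozen=True)
class Segment:
    """A contiguous selection of a note's sentences, with provenance.

    ``sentence_span`` is an inclusive (start, end) index pair into the
    note's sentence list.  For keyword segments ``match_info`` holds the
    matched keyword strings; for retrieval segments it holds
    (sentence_index, similarity_score) pairs.
    """

    note_id: str
    sentence_span: tuple[int, int]
    text: str
    source_method: str  # "regex" | "rag" | "baseline"
    match_info: tuple = ()

    def __post_init__(self) -> None:
        a, b = self.sentence_span
        if a < 0 or b < a:
            raise ValueError(f"invalid sentence span {self.sentence_span}")


@dataclass(frozen=True)
class UnitAnnotation:
    """Aggregated annotation for one unit, with its vote counts.

    Invariants (checked at construction): NNF iff all counts are zero;
    YES iff n_yes > n_no; NO iff n_no > n_yes; UNDECIDED iff the Yes/No
    counts tie with at least one conclusive or Unknown vote present.
    """

    unit_id: str
    level: str  # "subject" | "visit"
    final_label: FinalLabel
    n_yes: int = 0
    n_no: int = 0
    n_unknown: int = 0

    def __post_init__(self) -> None:
        if min(self.n_yes, self.n_no, self.n_unknown) < 0:
            raise ValueError("vote counts must be non-negative")
        expected = _label_from_counts(self.n_yes, self.n_no, self.n_unknown)
        if self.final_label is not expected:
            raise ValueError(
                f"label {self.final_label} inconsistent with counts "
                f"({self.n_yes}, {self.n_no}, {self.n_unknown}): expected {expected}"
            )


def _label_from_counts(n_yes: int, n_no: int, n_unknown: int) -> FinalLabel:
    if n_yes == n_no == n_unknown == 0:
        return FinalLabel.NNF
    if n_yes > n_no:
        return FinalLabel.YES
    if n_no > n_yes:
        return FinalLabel.NO
    return FinalLabel.UNDECIDED
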