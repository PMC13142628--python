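"""Reading, writing and summarizing note and ICD-event tables.

Two tabular dialects are accepted for both tables: CSV and JSON-lines
(one record per line), chosen by file extension or forced with
``dialect=``.  Column names are fixed — notes: ``note_id, subject_id,
visit_id, note_date, text``; events: ``subject_id, code, event_date`` —
and dates are ISO-8601 at day resolution.
"""

from __future__ import annotations

import datetime
import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .records import ClinicalNote, ICDEvent

NOTE_COLUMNS = ("note_id", "subject_id", "visit_id", "note_date", "text")
EVENT_COLUMNS = ("subject_id", "code", "event_date")


class CorpusFormatError(ValueError):
    """The input file violates the corpus contract."""


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "jsonl"):
            raise ValueError(f"unknown dialect {dialect!r} (use 'csv' or 'jsonl')")
        return dialect
    return "jsonl" if path.suffix in (".jsonl", ".ndjson", ".json") else "csv"


def _read_table(path: Path, dialect: str) -> pd.DataFrame:
    try:
        if dialect == "csv":
            return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
        rows = [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
        return pd.DataFrame(rows)
    except (ValueError, pd.errors.ParserError) as exc:
        raise CorpusFormatError(f"cannot parse {path}: {exc}") from exc


def _parse_date(value, row: int, column: str, path: Path) -> datetime.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError as exc:
        raise CorpusFormatError(
            f"{path}, row {row}: malformed {column} {value!r} (expected ISO-8601 date)"
        ) from exc


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value) == ""


@dataclass
class NoteSet:
    """All well-formed notes of a cohort, plus the dropped-row count."""

    notes: list[ClinicalNote]
    n_dropped: int = 0

    def by_subject(self) -> dict[str, list[ClinicalNote]]:
        out: dict[str, list[ClinicalNote]] = {}
        for note in self.notes:
            out.setdefault(note.subject_id, []).append(note)
        return out

    def by_visit(self) -> dict[str, list[ClinicalNote]]:
        """Group by explicit visit id; notes without one are skipped."""
        out: dict[str, list[ClinicalNote]] = {}
        for note in self.notes:
            if note.visit_id is not None:
                out.setdefault(note.visit_id, []).append(note)
        return out

    def __len__(self) -> int:
        return len(self.notes)


def read_notes(path: str | Path, dialect: str | None = None) -> NoteSet:
    """Read clinical notes from a CSV or JSON-lines file.

    Rows missing ``note_id`` or ``subject_id`` are dropped and counted;
    a duplicate ``note_id`` or a malformed date is fatal.  Notes are
    returned sorted by (subject_id, note_date, note_id); undated notes
    sort first within their subject.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path, _infer_dialect(path, dialect))
    missing_cols = {"note_id", "subject_id", "text"} - set(df.columns)
    if missing_cols:
        raise CorpusFormatError(f"{path}: missing required columns {sorted(missing_cols)}")
    notes: list[ClinicalNote] = []
    seen: set[str] = set()
    n_dropped = 0
    for row_no, row in enumerate(df.to_dict("records")):
        if _missing(row.get("note_id")) or _missing(row.get("subject_id")):
            n_dropped += 1
            continue
        note_id = str(row["note_id"])
        if note_id in seen:
            raise CorpusFormatError(f"{path}: duplicate note_id {note_id!r}")
        seen.add(note_id)
        visit = row.get("visit_id")
        text = row.get("text")
        notes.append(
            ClinicalNote(
                note_id=note_id,
                subject_id=str(row["subject_id"]),
                visit_id=None if _missing(visit) else str(visit),
                note_date=_parse_date(row.get("note_date"), row_no, "note_date", path),
                text="" if _missing(text) else str(text),
            )
        )
    notes.sort(key=lambda n: (n.subject_id, n.note_date or datetime.date.min, n.note_id))
    return NoteSet(notes=notes, n_dropped=n_dropped)


def write_notes(notes: Iterable[ClinicalNote], path: str | Path, dialect: str | None = None) -> None:
    """Write notes as CSV or JSON-lines with the fixed column set."""
    path = Path(path)
    rows = [
        {
            "note_id": n.note_id,
            "subject_id": n.subject_id,
            "visit_id": n.visit_id,
            "note_date": None if n.note_date is None else n.note_date.isoformat(),
            "text": n.text,
        }
        for n in notes
    ]
    if _infer_dialect(path, dialect) == "csv":
        pd.DataFrame(rows, columns=list(NOTE_COLUMNS)).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")


def read_icd_events(path: str | Path, dialect: str | None = None) -> list[ICDEvent]:
    """Read reference diagnosis events; exact duplicate rows are deduplicated.

    A malformed ``event_date`` is fatal with its row number.  A subject may
    legitimately carry several dated events of the same code.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path, _infer_dialect(path, dialect))
    missing_cols = {"subject_id", "code"} - set(df.columns)
    if missing_cols:
        raise CorpusFormatError(f"{path}: missing required columns {sorted(missing_cols)}")
    events: list[ICDEvent] = []
    seen: set[tuple] = set()
    for row_no, row in enumerate(df.to_dict("records")):
        if _missing(row.get("subject_id")) or _missing(row.get("code")):
            continue
        ev = ICDEvent(
            subject_id=str(row["subject_id"]),
            code=str(row["code"]),
            event_date=_parse_date(row.get("event_date"), row_no, "event_date", path),
        )
        key = (ev.subject_id, ev.code, ev.event_date)
        if key in seen:
            continue
        seen.add(key)
        events.append(ev)
    return events


def write_icd_events(events: Iterable[ICDEvent], path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    rows = [
        {
            "subject_id": e.subject_id,
            "code": e.code,
            "event_date": None if e.event_date is None else e.event_date.isoformat(),
        }
        for e in events
    ]
    if _infer_dialect(path, dialect) == "csv":
        pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding reproduces descriptive-table
    percentages bit-exactly from their printed count pairs.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Descriptive counts and percentages for a cohort + keyword spec."""

    n_subjects_with_notes: int
    n_notes: int
    n_icd_positive: int
    pct_icd_positive: float
    n_keyword_subjects: int
    pct_keyword_subjects: float
    n_keyword_notes: int
    pct_keyword_notes: float
    n_visits: int | None = None
    n_keyword_visits: int | None = None
    pct_keyword_visits: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "extras" and v is not None}
        out.update(self.extras)
        return out


def summarize_cohort(
    notes: NoteSet | Sequence[ClinicalNote],
    events: Iterable[ICDEvent],
    matcher,
    subject_decimals: int = 1,
    note_decimals: int = 2,
) -> CohortSummary:
    """Descriptive cohort summary.

    Reports: subjects with >= 1 note; reference-positive subjects among
    them (percentage at ``subject_decimals``); and subjects, visits and
    notes with >= 1 keyword match (subject percentage at
    ``subject_decimals``, visit/note percentages at ``note_decimals``).
    ``matcher`` is a compiled keyword pattern
    (:func:`phenonote.regex_filter.compile_pattern`).
    """
    note_list = notes.notes if isinstance(notes, NoteSet) else list(notes)
    subjects = {n.subject_id for n in note_list}
    if not subjects:
        raise ValueError("cohort has no subjects with notes")
    positive_subjects = {e.subject_id for e in events} & subjects
    matched_notes = [n for n in note_list if matcher.search(n.text)]
    matched_subjects = {n.subject_id for n in matched_notes}
    visits = {n.visit_id for n in note_list if n.visit_id is not None}
    matched_visits = {n.visit_id for n in matched_notes if n.visit_id is not None}
    summary = CohortSummary(
        n_subjects_with_notes=len(subjects),
        n_notes=len(note_list),
        n_icd_positive=len(positive_subjects),
        pct_icd_positive=percentage(len(positive_subjects), len(subjects), subject_decimals),
        n_keyword_subjects=len(matched_subjects),
        pct_keyword_subjects=percentage(len(matched_subjects), len(subjects), subject_decimals),
        n_keyword_notes=len(matched_notes),
        pct_keyword_notes=percentage(len(matched_notes), len(note_list), note_decimals),
    )
    if visits:
        summary.n_visits = len(visits)
        summary.n_keyword_visits = len(matched_visits)
        summary.pct_keyword_visits = percentage(len(matched_visits), len(visits), note_decimals)
    return summary
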