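"""Segment classification: prompt construction, backends, label parsing.

Each pre-filtered segment is wrapped in a zero- or few-shot prompt asking
for a one-word answer — Yes, No, or Unknown — and sent to a backend
satisfying :class:`Backend`.  The bundled :class:`MockBackend` is a
deterministic offline stand-in whose rules are shared with the synthetic
cohort's sentence templates: a segment carrying an affirmative marker is
Yes, a negation marker (without an affirmative one) is No, anything else
is Unknown.  Because the generator plants exactly those markers, every
expected label on synthetic data is known by construction.
"""

from __future__ import annotations

import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .config import TaskConfig
from .records import Segment, SegmentLabel

#: Marker vocabularies shared with the synthetic generator's templates.
AFFIRMATIVE_MARKERS: tuple[str, ...] = ("confirmed", "consistent with")
NEGATION_MARKERS: tuple[str, ...] = ("no evidence of", "ruled out")

_SEGMENT_HEADER = "Text:"
_ANSWER_HEADER = "Answer:"


@dataclass(frozen=True)
class ShotExample:
    """One worked example embedded in a few-shot prompt."""

    text: str
    label: SegmentLabel


@runtime_checkable
class Backend(Protocol):
    """Contract for pluggable classifier backends."""

    name: str
    deterministic: bool

    def classify(self, prompt: str) -> str:
        """Return the backend's raw response string for ``prompt``."""
        ...


class BackendError(RuntimeError):
    """A backend call failed permanently."""


class MockBackend:
    """Deterministic offline backend driven by marker tokens.

    Scans only the final ``Text:`` block of the prompt (so markers inside
    shot examples cannot leak into the decision): affirmative marker ->
    "Yes"; negation marker -> "No"; otherwise "Unknown".
    """

    name = "mock"
    deterministic = True

    def classify(self, prompt: str) -> str:
        block = prompt.rsplit(_SEGMENT_HEADER, 1)[-1]
        block = block.rsplit(_ANSWER_HEADER, 1)[0].lower()
        if any(marker in block for marker in AFFIRMATIVE_MARKERS):
            return "Yes"
        if any(marker in block for marker in NEGATION_MARKERS):
            return "No"
        return "Unknown"


def build_prompt(
    segment_text: str,
    target_variable: str,
    examples: Sequence[ShotExample] = (),
) -> str:
    """Build the classification prompt for one segment.

    ``examples`` must be balanced: equal numbers of YES, NO and UNKNOWN
    examples (n of each for n-shot prompting; empty for zero-shot).  The
    examples appear in fixed order — all YES, then all NO, then all
    UNKNOWN — so identical inputs always produce a byte-identical prompt.
    """
    by_label = {label: [e for e in examples if e.label is label] for label in SegmentLabel}
    counts = {label: len(v) for label, v in by_label.items()}
    if len(set(counts.values())) > 1:
        raise ValueError(
            "unbalanced shot examples: "
            + ", ".join(f"{k.value}={v}" for k, v in counts.items())
        )
    lines = [
        "You are reviewing an excerpt from a patient's clinical note.",
        f"Question: does the excerpt indicate that the patient has {target_variable}?",
        "Respond with exactly one word: Yes, No, or Unknown.",
        "",
    ]
    for label in (SegmentLabel.YES, SegmentLabel.NO, SegmentLabel.UNKNOWN):
        for ex in by_label[label]:
            lines += [_SEGMENT_HEADER, ex.text, f"{_ANSWER_HEADER} {label.value}", ""]
    lines += [_SEGMENT_HEADER, segment_text, _ANSWER_HEADER]
    return "\n".join(lines)


_LABEL_TOKEN = re.compile(r"\b(yes|no|unknown)\b", re.IGNORECASE)


def parse_label(raw: str) -> SegmentLabel:
    """Map a raw backend response to a label; never raises.

    The first standalone yes/no/unknown token (case-insensitive) wins;
    an unresolvable response conservatively maps to UNKNOWN.
    """
    m = _LABEL_TOKEN.search(raw)
    if m is None:
        return SegmentLabel.UNKNOWN
    return SegmentLabel(m.group(1).capitalize())


def classify_segments(
    segments_by_unit: Mapping[str, Sequence[Segment]],
    backend: Backend,
    task: TaskConfig,
    examples: Sequence[ShotExample] = (),
    retries: int = 2,
) -> dict[str, list[tuple[Segment, SegmentLabel]]]:
    """Classify every segment of every unit.

    Each backend call is retried up to ``retries`` extra times.  If a call
    still fails and the backend has never succeeded in this run, it is
    treated as permanently unavailable and a :class:`BackendError` naming
    the unit and segment is raised; after at least one success, a failing
    segment degrades to UNKNOWN instead.
    """
    if examples and len(examples) != 3 * task.shots_n:
        raise ValueError(
            f"expected {3 * task.shots_n} shot examples for shots_n={task.shots_n}, "
            f"got {len(examples)}"
        )
    results: dict[str, list[tuple[Segment, SegmentLabel]]] = {}
    ever_succeeded = False
    for unit, segments in segments_by_unit.items():
        labeled: list[tuple[Segment, SegmentLabel]] = []
        for seg in segments:
            prompt = build_prompt(seg.text, task.target_variable, examples)
            raw = None
            for _ in range(1 + retries):
                try:
                    raw = backend.classify(prompt)
                    ever_succeeded = True
                    break
                except Exception:
                    continue
            if raw is None:
                if not ever_succeeded:
                    raise BackendError(
                        f"backend {backend.name!r} unavailable "
                        f"(unit {unit!r}, note {seg.note_id!r})"
                    )
                labeled.append((seg, SegmentLabel.UNKNOWN))
            else:
                labeled.append((seg, parse_label(raw)))
        results[unit] = labeled
    return results


def baseline_segments(
    notes_by_unit: Mapping[str, Sequence],
    max_chars: int = 8000,
) -> tuple[dict[str, list[Segment]], set[str]]:
    """Non-pre-filtered baseline: one segment per note, whole text.

    The note text is truncated to ``max_chars`` keeping the head, mimicking
    a context-window cut-off.  Notes with empty text contribute nothing;
    units with only empty notes land in the NNF set.
    """
    segments_by_unit: dict[str, list[Segment]] = {}
    nnf: set[str] = set()
    for unit, notes in notes_by_unit.items():
        segs = [
            Segment(
                note_id=note.note_id,
                sentence_span=(0, 0),
                text=note.text[:max_chars],
                source_method="baseline",
            )
            for note in notes
            if note.text.strip()
        ]
        if segs:
            segments_by_unit[unit] = segs
        else:
            nnf.add(unit)
    return segments_by_unit, nnf


BACKENDS: dict[str, type] = {"mock": MockBackend}


def get_backend(name: str) -> Backend:
    """Instantiate a registered backend by name."""
    try:
        return BACKENDS[name]()
    except KeyError:
        raise KeyError(f"unknown backend {name!r}; registered: {sorted(BACKENDS)}") from None
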