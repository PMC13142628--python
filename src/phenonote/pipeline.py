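"""End-to-end orchestration: pre-filter → classify → vote → evaluate.

The stages are plain functions over in-memory collections; this module
wires them for the common cases (subject-level annotation of a whole
cohort, and per-event windowed annotation for time-sensitive evaluation)
so the CLI, the examples and the tests all run the same code path.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .aggregate import annotate_events, annotate_units, majority_vote
from .classify import Backend, ShotExample, classify_segments, get_backend
from .config import KeywordSpec, TaskConfig
from .io import NoteSet
from .keywords import EXAMPLE_KEYWORD_SPECS
from .metrics import (
    EvalReport,
    TimeSensitiveReport,
    TruthSet,
    model_metrics,
    partition_outcomes,
    system_metrics,
    time_sensitive_sensitivity,
)
from .rag_filter import Embedder, HashingEmbedder, build_rag_segments
from .records import ClinicalNote, ICDEvent, Segment, SegmentLabel, UnitAnnotation
from .regex_filter import compile_pattern, filter_cohort_regex
from .simulate import affirmative_sentence, negated_sentence, pending_sentence


def resolve_keyword_spec(task: TaskConfig, keyword_spec: KeywordSpec | None) -> KeywordSpec:
    if keyword_spec is not None:
        return keyword_spec
    if task.target_variable in EXAMPLE_KEYWORD_SPECS:
        return EXAMPLE_KEYWORD_SPECS[task.target_variable]
    raise ValueError(
        f"no keyword spec supplied and no example spec for {task.target_variable!r}"
    )


def build_segments(
    notes_by_unit: Mapping[str, list[ClinicalNote]],
    task: TaskConfig,
    keyword_spec: KeywordSpec | None = None,
    embedder: Embedder | None = None,
) -> tuple[dict[str, list[Segment]], set[str]]:
    """Run the configured pre-filter over every unit's notes."""
    if task.method == "regex":
        matcher = compile_pattern(resolve_keyword_spec(task, keyword_spec))
        return filter_cohort_regex(notes_by_unit, matcher)
    return build_rag_segments(
        notes_by_unit,
        task.target_variable,
        task.rag_top_s,
        task.rag_threshold,
        embedder or HashingEmbedder(),
    )


def default_shot_examples(task: TaskConfig, keyword_spec: KeywordSpec | None = None) -> list[ShotExample]:
    """A balanced n-shot example set built from the template sentences."""
    if task.shots_n == 0:
        return []
    keyword = resolve_keyword_spec(task, keyword_spec).literal_synonyms[0]
    examples: list[ShotExample] = []
    for _ in range(task.shots_n):
        examples.append(ShotExample(affirmative_sentence(keyword), SegmentLabel.YES))
        examples.append(ShotExample(negated_sentence(keyword), SegmentLabel.NO))
        examples.append(ShotExample(pending_sentence(keyword), SegmentLabel.UNKNOWN))
    return examples


def annotate_cohort(
    notes_by_unit: Mapping[str, list[ClinicalNote]],
    task: TaskConfig,
    keyword_spec: KeywordSpec | None = None,
    backend: Backend | None = None,
    embedder: Embedder | None = None,
    examples: Sequence[ShotExample] | None = None,
    level: str | None = None,
) -> list[UnitAnnotation]:
    """Pre-filter, classify and vote for every unit; one annotation each."""
    backend = backend or get_backend(task.backend)
    if examples is None:
        examples = default_shot_examples(task, keyword_spec)
    segments, nnf = build_segments(notes_by_unit, task, keyword_spec, embedder)
    labeled = classify_segments(segments, backend, task, examples)
    return annotate_units(labeled, task.method, nnf, level=level or task.level)


@dataclass
class PipelineResult:
    """Everything one evaluated run produces."""

    annotations: list[UnitAnnotation]
    truth: TruthSet
    model: EvalReport
    system: EvalReport
    time_sensitive: TimeSensitiveReport | None = None
    task: TaskConfig | None = None

    def annotations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "unit_id": a.unit_id,
                    "level": a.level,
                    "final_label": a.final_label.value,
                    "n_yes": a.n_yes,
                    "n_no": a.n_no,
                    "n_unknown": a.n_unknown,
                }
                for a in self.annotations
            ]
        )

    def report_dict(self) -> dict:
        out: dict = {
            "model": self.model.to_dict(),
            "system": self.system.to_dict(),
        }
        if self.time_sensitive is not None:
            out["time_sensitive"] = self.time_sensitive.to_dict()
        if self.task is not None:
            out["task"] = self.task.model_dump()
        return out


def run_pipeline(
    notes: NoteSet | Sequence[ClinicalNote],
    events: Sequence[ICDEvent],
    task: TaskConfig,
    keyword_spec: KeywordSpec | None = None,
    backend: Backend | None = None,
    embedder: Embedder | None = None,
    truth: TruthSet | None = None,
) -> PipelineResult:
    """Run the full pipeline and evaluate it against the event truth.

    Subject-level annotation and model/system metrics are always computed;
    subjects present in the truth file but without any notes are excluded
    from the evaluation denominators (they are not annotatable units).
    When ``task.level == "visit"`` and ``task.window_days`` is set, the
    per-event time-sensitive sensitivities are computed as well from
    independent windowed pipeline runs around each dated event.
    A pre-built ``truth`` (e.g. admission-level) may override the default
    subject-level truth derived from the events.
    """
    note_list = notes.notes if isinstance(notes, NoteSet) else list(notes)
    by_subject: dict[str, list[ClinicalNote]] = {}
    for n in note_list:
        by_subject.setdefault(n.subject_id, []).append(n)
    if truth is None:
        truth = TruthSet.from_events(events, by_subject.keys())
    annotations = annotate_cohort(
        by_subject, task, keyword_spec, backend, embedder, level="subject"
    )
    sets = partition_outcomes(annotations, truth)
    result = PipelineResult(
        annotations=annotations,
        truth=truth,
        model=model_metrics(sets, truth),
        system=system_metrics(sets, truth),
        task=task,
    )
    if task.level == "visit" and task.window_days:
        dated = [e for e in events if e.event_date is not None and e.subject_id in by_subject]

        def annotate_window(selected: list[ClinicalNote], unit_id: str) -> UnitAnnotation:
            anns = annotate_cohort(
                {unit_id: selected}, task, keyword_spec, backend, embedder, level="visit"
            )
            return anns[0]

        outcomes = annotate_events(by_subject, dated, task.window_days, annotate_window)
        result.time_sensitive = time_sensitive_sensitivity(outcomes, task.window_days)
    return result


__all__ = [
    "annotate_cohort",
    "build_segments",
    "default_shot_examples",
    "majority_vote",
    "PipelineResult",
    "resolve_keyword_spec",
    "run_pipeline",
]
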