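"""Evaluation against an ICD-code reference standard.

Two evaluation modes differ only in how "no notes found" (NNF) units are
counted.  Writing M_ICD / N_ICD for the reference positive / negative
unit sets, M_LLM for units annotated Yes, N_LLM for units annotated No or
Undecided, and N_NNF for NNF units:

* **model** mode scores only units for which relevant notes were found:
  the evaluated cohorts are M_ICD,eval = M_ICD − N_NNF and
  N_ICD,eval = N_ICD − N_NNF, and
  sensitivity = |M_LLM ∩ M_ICD,eval| / |M_ICD,eval|,
  specificity = |N_LLM ∩ N_ICD,eval| / |N_ICD,eval|.
* **system** mode scores the whole cohort end to end: an NNF outcome for a
  true positive is a pipeline failure (false negative) and for a true
  negative a correct rejection (true negative), so
  sensitivity = |M_LLM ∩ M_ICD| / |M_ICD| and
  specificity = |(N_LLM ∪ N_NNF) ∩ N_ICD| / |N_ICD|.

Precision |M_LLM ∩ M_ICD| / |M_LLM| is the same formula in both modes;
F1 is the harmonic mean of the mode's sensitivity and precision.

Time-sensitive evaluation scores each dated diagnosis event of the
positive cohort from the notes inside a window centred on the event date:
with N_c events annotated Yes, N_w annotated No or Undecided, and N_nn
NNF, model sensitivity is N_c/(N_c+N_w) and system sensitivity
N_c/(N_c+N_w+N_nn).  Specificity is undefined by design for this mode:
negative subjects have no diagnosis date to anchor a window on.

A metric whose denominator is empty is reported as None together with a
reason string — never silently as zero.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from .records import FinalLabel, ICDEvent, UnitAnnotation


@dataclass(frozen=True)
class TruthSet:
    """Reference-standard positive/negative unit-id sets (disjoint)."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"units both positive and negative: {sorted(overlap)[:5]}")

    @classmethod
    def from_events(cls, events: Iterable[ICDEvent], all_units: Iterable[str]) -> "TruthSet":
        """Positives are units with >= 1 event; the rest of ``all_units`` are negatives."""
        pos = {ev.subject_id for ev in events}
        units = set(all_units)
        return cls(frozenset(pos & units), frozenset(units - pos))

    @property
    def units(self) -> frozenset[str]:
        return self.positives | self.negatives


@dataclass(frozen=True)
class OutcomeSets:
    """Partition of annotated units by final label."""

    m_llm: frozenset[str]   # annotated Yes
    n_llm: frozenset[str]   # annotated No or Undecided
    n_nnf: frozenset[str]   # no notes found


@dataclass
class EvalReport:
    """Metric bundle for one evaluation mode.

    Undefined metrics are None with an entry in ``undefined`` explaining
    why.  ``counts`` carries the underlying set sizes.
    """

    mode: str  # "model" | "system"
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    counts: dict[str, int]
    undefined: dict[str, str] = field(default_factory=dict)

    def to_dict(self, decimals: int = 4) -> dict:
        def fmt(x: float | None) -> float | None:
            return None if x is None else round(x, decimals)

        return {
            "mode": self.mode,
            "sensitivity": fmt(self.sensitivity),
            "specificity": fmt(self.specificity),
            "precision": fmt(self.precision),
            "f1": fmt(self.f1),
            "counts": dict(self.counts),
            "undefined": dict(self.undefined),
        }


@dataclass
class TimeSensitiveReport:
    """Per-diagnosis-event outcome counts and the two sensitivities."""

    window_days: int
    n_correct: int       # events annotated Yes
    n_wrong: int         # events annotated No or Undecided
    n_no_notes: int      # events with no notes in the window
    sens_model: float | None
    sens_system: float | None
    undefined: dict[str, str] = field(default_factory=dict)

    def to_dict(self, decimals: int = 4) -> dict:
        return {
            "window_days": self.window_days,
            "n_correct": self.n_correct,
            "n_wrong": self.n_wrong,
            "n_no_notes": self.n_no_notes,
            "sens_model": None if self.sens_model is None else round(self.sens_model, decimals),
            "sens_system": None if self.sens_system is None else round(self.sens_system, decimals),
            "undefined": dict(self.undefined),
        }


def partition_outcomes(
    annotations: Sequence[UnitAnnotation],
    truth: TruthSet,
) -> OutcomeSets:
    """Split annotated units into Yes / non-positive / NNF sets.

    Every annotated unit must appear in the truth set; the three returned
    sets are disjoint and cover exactly the annotated units.
    """
    unknown = [a.unit_id for a in annotations if a.unit_id not in truth.units]
    if unknown:
        raise ValueError(f"annotated units absent from truth: {sorted(unknown)[:5]}")
    seen = Counter(a.unit_id for a in annotations)
    dupes = [u for u, c in seen.items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate annotations for units: {sorted(dupes)[:5]}")
    m_llm = frozenset(a.unit_id for a in annotations if a.final_label is FinalLabel.YES)
    n_llm = frozenset(
        a.unit_id for a in annotations
        if a.final_label in (FinalLabel.NO, FinalLabel.UNDECIDED)
    )
    n_nnf = frozenset(a.unit_id for a in annotations if a.final_label is FinalLabel.NNF)
    return OutcomeSets(m_llm, n_llm, n_nnf)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def _f1(sens: float | None, prec: float | None) -> float | None:
    if sens is None or prec is None or sens + prec == 0:
        return None
    return 2 * sens * prec / (sens + prec)


def _base_counts(sets: OutcomeSets, truth: TruthSet) -> dict[str, int]:
    return {
        "n_icd_positive": len(truth.positives),
        "n_icd_negative": len(truth.negatives),
        "n_llm_positive": len(sets.m_llm),
        "n_llm_nonpositive": len(sets.n_llm),
        "n_nnf": len(sets.n_nnf),
    }


def model_metrics(sets: OutcomeSets, truth: TruthSet) -> EvalReport:
    """Model-mode metrics: NNF units are excluded from the denominators."""
    pos_eval = truth.positives - sets.n_nnf
    neg_eval = truth.negatives - sets.n_nnf
    sens = _ratio(len(sets.m_llm & pos_eval), len(pos_eval))
    spec = _ratio(len(sets.n_llm & neg_eval), len(neg_eval))
    prec = _ratio(len(sets.m_llm & truth.positives), len(sets.m_llm))
    counts = _base_counts(sets, truth)
    counts["n_icd_positive_eval"] = len(pos_eval)
    counts["n_icd_negative_eval"] = len(neg_eval)
    report = EvalReport("model", sens, spec, prec, _f1(sens, prec), counts)
    if sens is None:
        report.undefined["sensitivity"] = "no evaluated reference-positive units"
    if spec is None:
        report.undefined["specificity"] = "no evaluated reference-negative units"
    if prec is None:
        report.undefined["precision"] = "no units annotated Yes"
    if report.f1 is None:
        report.undefined["f1"] = "sensitivity or precision undefined or both zero"
    return report


def system_metrics(sets: OutcomeSets, truth: TruthSet) -> EvalReport:
    """System-mode metrics: NNF counts against the full cohort."""
    sens = _ratio(len(sets.m_llm & truth.positives), len(truth.positives))
    spec = _ratio(len((sets.n_llm | sets.n_nnf) & truth.negatives), len(truth.negatives))
    prec = _ratio(len(sets.m_llm & truth.positives), len(sets.m_llm))
    counts = _base_counts(sets, truth)
    report = EvalReport("system", sens, spec, prec, _f1(sens, prec), counts)
    if sens is None:
        report.undefined["sensitivity"] = "no reference-positive units"
    if spec is None:
        report.undefined["specificity"] = "no reference-negative units"
    if prec is None:
        report.undefined["precision"] = "no units annotated Yes"
    if report.f1 is None:
        report.undefined["f1"] = "sensitivity or precision undefined or both zero"
    return report


def time_sensitive_sensitivity(
    event_outcomes: Mapping[tuple, FinalLabel] | Sequence[FinalLabel],
    window_days: int,
) -> TimeSensitiveReport:
    """Per-event sensitivities from the outcomes of all dated events.

    Accepts either the mapping produced by
    :func:`phenonote.aggregate.annotate_events` (values may be
    UnitAnnotations or FinalLabels) or a plain outcome sequence.
    """
    if isinstance(event_outcomes, Mapping):
        values = list(event_outcomes.values())
    else:
        values = list(event_outcomes)
    labels = [v.final_label if isinstance(v, UnitAnnotation) else v for v in values]
    counts = Counter(labels)
    n_c = counts[FinalLabel.YES]
    n_w = counts[FinalLabel.NO] + counts[FinalLabel.UNDECIDED]
    n_nn = counts[FinalLabel.NNF]
    report = TimeSensitiveReport(
        window_days=window_days,
        n_correct=n_c,
        n_wrong=n_w,
        n_no_notes=n_nn,
        sens_model=_ratio(n_c, n_c + n_w),
        sens_system=_ratio(n_c, n_c + n_w + n_nn),
    )
    if not labels:
        report.undefined["sens_model"] = "no diagnosis events to evaluate"
        report.undefined["sens_system"] = "no diagnosis events to evaluate"
    elif report.sens_model is None:
        report.undefined["sens_model"] = "every event window was empty (all NNF)"
    return report
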