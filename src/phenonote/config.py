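"""Task and generator configuration models.

Configurations are pydantic models so that YAML/JSON task files are
validated on load: a retrieval task must carry its retrieval parameters,
rates live in [0, 1], and so on.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class KeywordSpec(BaseModel):
    """Keyword definition for one target variable.

    ``literal_synonyms`` are matched case-insensitively inside word
    boundaries; ``flexible_patterns`` are regular-expression templates taken
    verbatim (e.g. ``insulin[- ]dependent`` for the optional-hyphen variant).
    The union of the two lists must be non-empty.
    """

    target_variable: str
    literal_synonyms: list[str] = Field(default_factory=list)
    flexible_patterns: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _non_empty(self) -> "KeywordSpec":
        if not self.literal_synonyms and not self.flexible_patterns:
            raise ValueError("KeywordSpec needs at least one synonym or pattern")
        return self


class TaskConfig(BaseModel):
    """One annotation task: target variable, pre-filter method, parameters.

    ``rag_top_s`` / ``rag_threshold`` are required iff ``method == "rag"``.
    ``window_days`` is the total window length n (notes within floor(n/2)
    days either side of an anchor date are selected) and is required for
    visit-level analysis without explicit visit identifiers.
    """

    target_variable: str
    method: Literal["regex", "rag"] = "regex"
    rag_top_s: int | None = None
    rag_threshold: float | None = None
    shots_n: int = 0
    window_days: int | None = None
    level: Literal["subject", "visit"] = "subject"
    backend: str = "mock"
    embedder: str = "hashing"
    seed: int = 0

    @field_validator("shots_n")
    @classmethod
    def _shots_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("shots_n must be non-negative")
        return v

    @field_validator("window_days")
    @classmethod
    def _window_pos(cls, v: int | None) -> int | None:
        if v is not None and v <= 0:
            raise ValueError("window_days must be positive")
        return v

    @model_validator(mode="after")
    def _rag_fields(self) -> "TaskConfig":
        if self.method == "rag":
            if self.rag_top_s is None or self.rag_threshold is None:
                raise ValueError("rag method requires rag_top_s and rag_threshold")
            if self.rag_top_s < 1:
                raise ValueError("rag_top_s must be >= 1")
            if not -1.0 <= self.rag_threshold <= 1.0:
                raise ValueError("rag_threshold must lie in [-1, 1]")
        return self


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic longitudinal cohort generator.

    ``affirmative_rate`` (q) is the per-note probability that a positive
    subject's in-window note carries an affirmative mention of the target;
    ``negation_rate`` is the per-note probability a negative subject's note
    carries an explicitly negated mention; ``pending_rate`` is the per-note
    probability of a pending/ambiguous mention (either group).  Generation
    is a pure function of ``seed``.
    """

    n_subjects: int = 200
    prevalence: float = 0.378
    notes_per_subject: tuple[int, int] = (2, 6)
    sentences_per_note: tuple[int, int] = (4, 8)
    affirmative_rate: float = 0.6
    negation_rate: float = 0.3
    pending_rate: float = 0.1
    noise_vocab_size: int = 30
    window_days: int = 20
    events_per_positive: tuple[int, int] = (1, 2)
    in_window_fraction: float = 1.0
    seed: int = 0

    @field_validator("prevalence", "affirmative_rate", "negation_rate",
                     "pending_rate", "in_window_fraction")
    @classmethod
    def _rate(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        return v

    @field_validator("notes_per_subject", "sentences_per_note", "events_per_positive")
    @classmethod
    def _range(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if lo < 1 or hi < lo:
            raise ValueError("range must satisfy 1 <= lo <= hi")
        return v

    @model_validator(mode="after")
    def _has_positives(self) -> "SyntheticConfig":
        if int(round(self.prevalence * self.n_subjects)) < 1:
            raise ValueError("prevalence * n_subjects must yield at least one positive")
        return self


def _load_mapping(path: str | Path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_keyword_spec(path: str | Path) -> KeywordSpec:
    """Load a KeywordSpec from a YAML or JSON file."""
    return KeywordSpec.model_validate(_load_mapping(path))


def load_task_config(path: str | Path) -> TaskConfig:
    """Load a TaskConfig from a YAML or JSON file."""
    return TaskConfig.model_validate(_load_mapping(path))
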