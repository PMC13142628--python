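import datetime

import pytest
from hypothesis import HealthCheck, settings

from phenonote import (
    ClinicalNote,
    FinalLabel,
    KeywordSpec,
    TaskConfig,
    UnitAnnotation,
    compile_pattern,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def metastasis_spec() -> KeywordSpec:
    return KeywordSpec(
        target_variable="metastasis",
        literal_synonyms=["metastasis", "metastatic"],
    )


@pytest.fixture(scope="session")
def metastasis_matcher(metastasis_spec):
    return compile_pattern(metastasis_spec)


@pytest.fixture
def regex_task() -> TaskConfig:
    return TaskConfig(target_variable="metastasis", method="regex")


@pytest.fixture
def rag_task() -> TaskConfig:
    return TaskConfig(
        target_variable="metastasis", method="rag", rag_top_s=3, rag_threshold=0.25
    )


def note(note_id: str, subject: str = "S1", text: str = "", day: int | None = 0, visit=None):
    """Shorthand note builder: ``day`` is an offset from 2020-01-01."""
    date = None if day is None else datetime.date(2020, 1, 1) + datetime.timedelta(days=day)
    return ClinicalNote(note_id=note_id, subject_id=subject, text=text, note_date=date, visit_id=visit)


def annotation(unit_id: str, label: FinalLabel, n_yes=0, n_no=0, n_unknown=0, level="subject"):
    return UnitAnnotation(
        unit_id=unit_id, level=level, final_label=label,
        n_yes=n_yes, n_no=n_no, n_unknown=n_unknown,
    )
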