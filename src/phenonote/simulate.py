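"""Synthetic longitudinal cohort generator.

Generates subjects with per-subject note streams, dated reference
diagnosis events for the positive fraction, and note text assembled from
four sentence templates whose downstream labels are known by
construction, because the templates share their marker vocabulary with
the mock classifier backend:

* affirmative — contains a target keyword *and* an affirmative marker
  (classified Yes),
* negated — keyword plus a negation marker (classified No),
* pending — keyword but neither marker (classified Unknown),
* noise — no keyword at all (never pre-filtered).

Positive subjects plant an affirmative sentence in each in-window note
independently with probability q (``affirmative_rate``), so the chance a
positive subject is annotated Yes is analytically 1 − (1 − f·q)^k for k
notes of which a fraction f fall in the event window — the closed form
:func:`expected_system_sensitivity` returns and the end-to-end tests
recover.  Negative subjects receive negated / pending / noise notes only
and can therefore never be annotated Yes.

Generation is a pure function of ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import AFFIRMATIVE_MARKERS, NEGATION_MARKERS
from .config import KeywordSpec, SyntheticConfig
from .keywords import EXAMPLE_KEYWORD_SPECS
from .records import ClinicalNote, ICDEvent

EPOCH = datetime.date(2020, 1, 1)
DEFAULT_CODE = "C79.9"

_BASE_NOISE_WORDS = [
    "fatigue", "headache", "dizziness", "nausea", "insomnia", "backache",
    "congestion", "heartburn", "stiffness", "bruising", "cramping", "tingling",
    "itching", "hoarseness", "drowsiness", "restlessness", "soreness",
    "weakness", "chills", "sweats", "palpitations", "wheezing", "swelling",
    "numbness", "tenderness", "dryness", "twitching", "aching", "burning",
    "throbbing",
]


def _noise_vocab(size: int) -> list[str]:
    vocab = list(_BASE_NOISE_WORDS[:size])
    for i in range(len(vocab), size):
        vocab.append(f"symptom{i}")
    return vocab


def affirmative_sentence(keyword: str) -> str:
    return f"Recent imaging confirmed {keyword} in the thoracic region."


def negated_sentence(keyword: str) -> str:
    return f"Surveillance imaging showed no evidence of {keyword} at this visit."


def pending_sentence(keyword: str) -> str:
    return f"Biopsy to evaluate possible {keyword} is pending at this time."


def noise_sentence(word: str) -> str:
    return f"Patient reports stable {word} and routine follow up was arranged."


@dataclass
class Cohort:
    """A generated cohort: notes, reference events, and generative truth.

    ``truth`` has one row per note: subject_id, note_id, is_positive,
    mention (affirmative/negated/pending/none) and in_window.
    """

    notes: list[ClinicalNote]
    events: list[ICDEvent]
    truth: pd.DataFrame
    keyword_spec: KeywordSpec
    config: SyntheticConfig

    def notes_by_subject(self) -> dict[str, list[ClinicalNote]]:
        out: dict[str, list[ClinicalNote]] = {}
        for note in self.notes:
            out.setdefault(note.subject_id, []).append(note)
        return out

    @property
    def subject_ids(self) -> list[str]:
        return sorted({n.subject_id for n in self.notes})


def _assemble_note(rng, planted: str | None, n_sentences: int, vocab: list[str]) -> str:
    sentences = [noise_sentence(vocab[rng.integers(len(vocab))]) for _ in range(n_sentences)]
    if planted is not None:
        sentences[int(rng.integers(n_sentences))] = planted
    return " ".join(sentences)


def generate_cohort(config: SyntheticConfig, keyword_spec: KeywordSpec | None = None) -> Cohort:
    """Generate a cohort under ``config``; pure function of the seed."""
    spec = keyword_spec or EXAMPLE_KEYWORD_SPECS["metastasis"]
    keyword = spec.literal_synonyms[0]
    for template in (affirmative_sentence, negated_sentence, pending_sentence):
        _check_template(template(keyword), keyword)
    rng = np.random.default_rng(config.seed)
    vocab = _noise_vocab(config.noise_vocab_size)
    n_pos = int(round(config.prevalence * config.n_subjects))
    half = config.window_days // 2
    width = len(str(config.n_subjects))

    notes: list[ClinicalNote] = []
    events: list[ICDEvent] = []
    truth_rows: list[dict] = []
    note_counter = 0
    for idx in range(config.n_subjects):
        subject_id = f"S{idx + 1:0{width}d}"
        is_positive = idx < n_pos
        anchors: list[datetime.date] = []
        if is_positive:
            lo, hi = config.events_per_positive
            n_events = int(rng.integers(lo, hi + 1))
            # anchors spread so that event windows rarely overlap
            offsets = sorted(int(rng.integers(0, 720)) for _ in range(n_events))
            for off in offsets:
                anchor = EPOCH + datetime.timedelta(days=off)
                anchors.append(anchor)
                events.append(ICDEvent(subject_id=subject_id, code=DEFAULT_CODE, event_date=anchor))
        lo, hi = config.notes_per_subject
        n_notes = int(rng.integers(lo, hi + 1))
        slo, shi = config.sentences_per_note
        for _ in range(n_notes):
            note_counter += 1
            note_id = f"N{note_counter:06d}"
            n_sentences = int(rng.integers(slo, shi + 1))
            if is_positive:
                anchor = anchors[int(rng.integers(len(anchors)))]
                in_window = bool(rng.random() < config.in_window_fraction)
                if in_window:
                    note_date = anchor + datetime.timedelta(days=int(rng.integers(-half, half + 1)))
                else:
                    sign = 1 if rng.random() < 0.5 else -1
                    note_date = anchor + datetime.timedelta(
                        days=sign * int(rng.integers(half + 1, half + 61))
                    )
                if in_window and rng.random() < config.affirmative_rate:
                    mention = "affirmative"
                    planted = affirmative_sentence(keyword)
                elif rng.random() < config.pending_rate:
                    mention = "pending"
                    planted = pending_sentence(keyword)
                else:
                    mention, planted = "none", None
            else:
                note_date = EPOCH + datetime.timedelta(days=int(rng.integers(0, 720)))
                in_window = False
                u = rng.random()
                if u < config.negation_rate:
                    mention, planted = "negated", negated_sentence(keyword)
                elif u < config.negation_rate + config.pending_rate:
                    mention, planted = "pending", pending_sentence(keyword)
                else:
                    mention, planted = "none", None
            notes.append(
                ClinicalNote(
                    note_id=note_id,
                    subject_id=subject_id,
                    note_date=note_date,
                    text=_assemble_note(rng, planted, n_sentences, vocab),
                )
            )
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "note_id": note_id,
                    "is_positive": is_positive,
                    "mention": mention,
                    "in_window": in_window,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "note_id", "is_positive", "mention", "in_window"])
    return Cohort(notes=notes, events=events, truth=truth, keyword_spec=spec, config=config)


def _check_template(sentence: str, keyword: str) -> None:
    low = sentence.lower()
    if keyword.lower() not in low:
        raise ValueError(f"template {sentence!r} lost keyword {keyword!r}")
    markers = AFFIRMATIVE_MARKERS + NEGATION_MARKERS
    if not any(m in low for m in markers) and "pending" not in low:
        raise ValueError(f"template {sentence!r} carries no recognisable cue")


def expected_system_sensitivity(config: SyntheticConfig) -> float:
    """Closed-form expected subject-level system sensitivity.

    A positive subject is annotated Yes iff at least one of its notes is
    affirmative; each note independently lands in an event window with
    probability f (``in_window_fraction``) and, if so, carries the
    affirmative template with probability q, so for k notes the miss
    probability is (1 − f·q)^k.  The returned value averages over k
    uniform on ``notes_per_subject``.
    """
    q = config.affirmative_rate * config.in_window_fraction
    lo, hi = config.notes_per_subject
    ks = np.arange(lo, hi + 1)
    return float(1.0 - np.mean((1.0 - q) ** ks))


def planted_multimention_note(
    n_mentions: int,
    keyword: str = "metastasis",
    note_id: str = "N-multi",
    subject_id: str = "S-multi",
    note_date: datetime.date = EPOCH,
) -> ClinicalNote:
    """A note with ``n_mentions`` well-separated affirmative mentions.

    Mentions sit four sentences apart so their three-sentence context
    windows neither overlap nor touch: the keyword branch emits
    ``n_mentions`` segments (votes) while the retrieval branch emits one.
    """
    if n_mentions < 1:
        raise ValueError("need at least one mention")
    vocab = _noise_vocab(10)
    total = 4 * (n_mentions - 1) + 2
    sentences = [noise_sentence(vocab[i % len(vocab)]) for i in range(total)]
    for m in range(n_mentions):
        sentences[4 * m] = affirmative_sentence(keyword)
    return ClinicalNote(
        note_id=note_id, subject_id=subject_id, note_date=note_date, text=" ".join(sentences)
    )
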