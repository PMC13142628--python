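"""Semantic-retrieval pre-filtering.

Alternative to the keyword branch for targets where an exhaustive synonym
list is hard to write: every sentence of a note is embedded and scored by
cosine similarity against the target-variable query, and the p sentences
(0 <= p <= s) that are simultaneously among the note's top-s scores and
strictly above the similarity threshold form that note's single segment.
A note therefore casts at most one vote regardless of how many mentions it
contains — the key behavioural contrast with the keyword branch.

The bundled :class:`HashingEmbedder` is a deterministic feature-hashing
bag-of-words embedder: it needs no model weights or network access and is
reproducible bit-for-bit across machines.  Any object satisfying
:class:`Embedder` (e.g. a sentence-transformer wrapper) can be plugged in
instead.
"""

from __future__ import annotations

import hashlib
import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .records import ClinicalNote, Segment
from .sentences import split_sentences


@runtime_checkable
class Embedder(Protocol):
    """Contract for pluggable sentence embedders."""

    name: str
    dimension: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        """Return an array of shape (len(texts), dimension); deterministic."""
        ...


_TOKEN = re.compile(r"[a-z0-9]+")


class HashingEmbedder:
    """Deterministic feature-hashing bag-of-words embedder.

    Tokens (lower-cased alphanumeric runs) are hashed with blake2b into
    ``dimension`` buckets with a sign bit, so identical text always maps to
    the identical vector and no vocabulary is stored.
    """

    def __init__(self, dimension: int = 256):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.name = f"hashing-bow-{dimension}"
        self.dimension = dimension

    def _bucket(self, token: str) -> tuple[int, float]:
        h = int.from_bytes(hashlib.blake2b(token.encode(), digest_size=8).digest(), "big")
        return h % self.dimension, 1.0 if (h >> 62) & 1 else -1.0

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dimension))
        for row, text in enumerate(texts):
            for token in _TOKEN.findall(text.lower()):
                idx, sign = self._bucket(token)
                out[row, idx] += sign
        return out


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two equal-length non-zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


@dataclass(frozen=True)
class ScoredSentence:
    index: int
    text: str
    score: float


def retrieve_sentences(
    note: ClinicalNote,
    query: str,
    s: int,
    threshold: float,
    embedder: Embedder,
) -> list[ScoredSentence]:
    """Retrieve the note's relevant sentences for ``query``.

    Returns the p sentences (0 <= p <= s) that are both among the s
    highest-scoring sentences of the note and *strictly* above
    ``threshold``, in descending score order with ties broken by earlier
    position.  Sentences with an empty embedding (no tokens) have no
    defined similarity and are never retrieved.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    sentences = split_sentences(note.text)
    if not sentences:
        return []
    vecs = embedder.embed([query] + sentences)
    qvec = vecs[0]
    if np.linalg.norm(qvec) == 0.0:
        raise ValueError(f"query {query!r} has an empty embedding")
    scored = []
    for i, sent in enumerate(sentences):
        svec = vecs[1 + i]
        if np.linalg.norm(svec) == 0.0:
            continue
        scored.append(ScoredSentence(i, sent, cosine_similarity(qvec, svec)))
    scored.sort(key=lambda r: (-r.score, r.index))
    return [r for r in scored[:s] if r.score > threshold]


def build_rag_segments(
    notes_by_unit: Mapping[str, list[ClinicalNote]],
    query: str,
    s: int,
    threshold: float,
    embedder: Embedder,
) -> tuple[dict[str, list[Segment]], set[str]]:
    """Run semantic retrieval over every unit's notes.

    Each note with p >= 1 retrieved sentences yields exactly one segment
    whose text keeps the retrieved sentences in document order (the
    classifier reads coherent context even when scores rank differently);
    ``match_info`` records the (index, score) pairs.  Units where every
    note has p = 0 land in the NNF set.
    """
    segments_by_unit: dict[str, list[Segment]] = {}
    nnf: set[str] = set()
    for unit, notes in notes_by_unit.items():
        segs: list[Segment] = []
        for note in notes:
            hits = retrieve_sentences(note, query, s, threshold, embedder)
            if not hits:
                continue
            in_order = sorted(hits, key=lambda r: r.index)
            segs.append(
                Segment(
                    note_id=note.note_id,
                    sentence_span=(in_order[0].index, in_order[-1].index),
                    text=" ".join(r.text for r in in_order),
                    source_method="rag",
                    match_info=tuple((r.index, r.score) for r in in_order),
                )
            )
        if segs:
            segments_by_unit[unit] = segs
        else:
            nnf.add(unit)
    return segments_by_unit, nnf
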