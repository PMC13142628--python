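"""Deterministic rule-based sentence splitting for clinical text.

Clinical notes are line-structured and full of abbreviations, and the
pipeline only needs *stable* sentence boundaries: segments are defined by
sentence indices, so the single requirement is that splitting is
deterministic and loses no text.  The rules, in order:

1. Line breaks always end a sentence (section headers, problem lists).
2. Within a line, a run of ``. ! ?`` followed by whitespace ends a
   sentence, unless the run is a single period attached to a known
   clinical/title abbreviation (``Dr.``, ``pt.``, ``e.g.`` ...).
3. Whitespace around sentences is stripped; nothing else is altered, so
   joining the sentences with single spaces reconstructs the input modulo
   inter-sentence whitespace.

Single capital letters are deliberately *not* treated as abbreviations
("A. B. C." is three sentences).
"""

from __future__ import annotations

import re

#: Tokens whose trailing period does not end a sentence (lower-case,
#: period-free form; multi-dot abbreviations keep their internal dots).
ABBREVIATIONS = frozenset({
    "dr", "mr", "mrs", "ms", "prof", "jr", "sr", "st",
    "pt", "pts", "dx", "hx", "fx", "tx", "rx", "sx",
    "vs", "etc", "approx", "dept", "appt", "wt", "ht",
    "e.g", "i.e", "resp", "neg", "pos",
})

_TERMINATOR = re.compile(r"([.!?]+)(\s+)")
_LAST_TOKEN = re.compile(r"([A-Za-z][A-Za-z.]*)\Z")


def _ends_with_abbreviation(chunk: str) -> bool:
    m = _LAST_TOKEN.search(chunk)
    if m is None:
        return False
    token = m.group(1).lower()
    return len(token) > 1 and token in ABBREVIATIONS


def _split_line(line: str) -> list[str]:
    sentences: list[str] = []
    start = 0
    for m in _TERMINATOR.finditer(line):
        if m.group(1) == "." and _ends_with_abbreviation(line[start:m.start(1)]):
            continue
        piece = line[start:m.end(1)].strip()
        if piece:
            sentences.append(piece)
        start = m.end()
    tail = line[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def split_sentences(text: str) -> list[str]:
    """Split ``text`` into an ordered list of sentences.

    Deterministic; empty or whitespace-only input yields ``[]``.
    """
    sentences: list[str] = []
    for line in text.splitlines():
        sentences.extend(_split_line(line))
    return sentences
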