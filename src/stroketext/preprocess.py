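"""Sentence segmentation with character spans.

Every extraction rule is applied within a single sentence, so segmentation
is the unit of scope for the whole engine: evidence split across two
sentences is invisible downstream by design. Radiology reports are heavily
line-structured (section headers such as ``FINDINGS:`` sit on their own
lines), so newlines are hard boundaries; within a line, a sentence ends at
a run of ``.!?`` followed by whitespace and an uppercase letter or digit.
Decimal numbers ("a 1.5 cm hypodensity") and a configurable list of
protected abbreviations never end a sentence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Sequence

__all__ = ["Sentence", "segment_sentences", "DEFAULT_ABBREVIATIONS"]

#: Abbreviations after which a period does not end the sentence. The
#: segmenter is dialect-sensitive, so this is configuration, not code.
DEFAULT_ABBREVIATIONS: tuple[str, ...] = (
    "Dr",
    "Mr",
    "Mrs",
    "Ms",
    "Prof",
    "vs",
    "e.g",
    "i.e",
    "approx",
    "Fig",
    "St",
)

# Sentence-final punctuation, then whitespace, then an upper-case letter or
# digit. A period inside a decimal is never followed by whitespace, so
# decimals are protected without a special case.
_BREAK_RE = re.compile(r"([.!?]+)(\s+)(?=[A-Z0-9])")


@dataclass(frozen=True)
class Sentence:
    """A sentence of one report, with its span in the original text.

    ``span`` is 0-based half-open: ``report_text[span[0]:span[1]] == text``.
    """

    report_id: str
    index: int
    text: str
    span: tuple[int, int]


def _ends_with_abbreviation(prefix: str, abbreviations: Sequence[str]) -> bool:
    low = prefix.lower()
    for abbr in abbreviations:
        a = abbr.lower()
        if low.endswith(a):
            before = len(low) - len(a) - 1
            if before < 0 or not low[before].isalnum():
                return True
    return False


def _split_line(
    line: str, offset: int, abbreviations: Sequence[str]
) -> Iterator[tuple[int, int]]:
    """Yield raw (start, end) spans of sentence candidates within a line."""
    pos = 0
    for m in _BREAK_RE.finditer(line):
        if _ends_with_abbreviation(line[: m.start(1)], abbreviations):
            continue
        yield offset + pos, offset + m.end(1)
        pos = m.end()
    yield offset + pos, offset + len(line)


def segment_sentences(
    text: str,
    report_id: str = "",
    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
) -> list[Sentence]:
    """Split report text into ordered, non-overlapping sentences.

    Returns sentences with strictly increasing spans whose texts tile the
    input up to the removed delimiter runs (newlines and inter-sentence
    whitespace). Empty or whitespace-only segments are dropped; an empty
    input yields an empty list. Deterministic.
    """
    sentences: list[Sentence] = []
    line_start = 0
    for line in text.split("\n"):
        for raw_start, raw_end in _split_line(line, line_start, abbreviations):
            segment = text[raw_start:raw_end]
            stripped = segment.strip()
            if stripped:
                start = raw_start + (len(segment) - len(segment.lstrip()))
                end = start + len(stripped)
                sentences.append(
                    Sentence(
                        report_id=report_id,
                        index=len(sentences),
                        text=stripped,
                        span=(start, end),
                    )
                )
        line_start += len(line) + 1
    return sentences
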