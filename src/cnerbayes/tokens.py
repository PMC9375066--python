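"""Offset-preserving word-punct tokenization and fragment-of-text construction.

A *fragment of text* (FoT) is the unit of classification: a target token plus
up to ``w`` context tokens on each side, labelled by the entity span the
target overlaps (or NON_CNE).  Title and abstract are tokenized
independently; context windows never cross the section boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

from .corpus import (AnnotatedDocument, ClassLabel, EntitySpan, Section,
                     label_for_etype)

logger = logging.getLogger(__name__)

#: Maximal runs of word characters OR maximal runs of non-word, non-space
#: characters — the word-punct tokenization contract.
TOKEN_PATTERN = re.compile(r"\w+|[^\w\s]+")

#: Supported context-window sizes (tokens on each side of the target).
WINDOWS = (0, 1, 2, 3)


@dataclass(frozen=True)
class Token:
    """A token with half-open character offsets into its section text."""

    surface: str
    start: int
    end: int
    section: Section = Section.ABSTRACT

    def __len__(self) -> int:  # characters
        return self.end - self.start

    def overlaps(self, span: EntitySpan) -> bool:
        return (span.section is self.section
                and max(self.start, span.start) < min(self.end, span.end))


@dataclass
class FoT:
    """A fragment of text: target token + context, with its class label."""

    target: Token
    left: tuple[Token, ...]
    right: tuple[Token, ...]
    window: int
    label: ClassLabel
    doc_id: str = ""

    @property
    def tokens(self) -> tuple[Token, ...]:
        """All member tokens in document order (left, target, right)."""
        return (*self.left, self.target, *self.right)

    @property
    def is_cne(self) -> bool:
        return self.label is not ClassLabel.NON_CNE


def tokenize(text: str, section: Section = Section.ABSTRACT) -> list[Token]:
    """Split text into word runs and punctuation runs, keeping offsets.

    Concatenating token surfaces and the skipped whitespace reproduces the
    input; tokens contain no whitespace and are ordered by start offset.
    """
    return [Token(m.group(), m.start(), m.end(), section)
            for m in TOKEN_PATTERN.finditer(text)]


def _label_for_token(token: Token, spans: Sequence[EntitySpan]) -> ClassLabel:
    # Overlap rule: any shared character assigns the span's type; among
    # several overlapping spans the longest wins, ties broken by leftmost.
    hits = [s for s in spans if token.overlaps(s)]
    if not hits:
        return ClassLabel.NON_CNE
    best = max(hits, key=lambda s: (s.end - s.start, -s.start))
    labels = {label_for_etype(s.etype) for s in hits}
    if len(labels) > 1:
        logger.warning(
            "token %r [%d:%d] overlaps spans of conflicting types %s; "
            "keeping %s (longest span)", token.surface, token.start, token.end,
            sorted(l.value for l in labels), label_for_etype(best.etype).value)
    return label_for_etype(best.etype)


def build_fots(tokens: Sequence[Token], spans: Sequence[EntitySpan],
               window: int, doc_id: str = "") -> list[FoT]:
    """Build exactly one FoT per token with truncated context windows.

    The label is the type of the entity span the target character-overlaps
    (NON_CNE when none); contexts are the ``window`` nearest tokens on each
    side, truncated at the section boundaries (no padding).
    """
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}, got {window}")
    fots = []
    for i, tok in enumerate(tokens):
        left = tuple(tokens[max(0, i - window):i])
        right = tuple(tokens[i + 1:i + 1 + window])
        fots.append(FoT(tok, left, right, window, _label_for_token(tok, spans),
                        doc_id))
    return fots


def document_fots(doc: AnnotatedDocument, window: int) -> list[FoT]:
    """All FoTs of a document: title first, then abstract, sections separate."""
    out: list[FoT] = []
    for section in (Section.TITLE, Section.ABSTRACT):
        tokens = tokenize(doc.section_text(section), section)
        spans = doc.section_spans(section)
        out.extend(build_fots(tokens, spans, window, doc.doc_id))
    return out
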