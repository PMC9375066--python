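"""CHEMDNER-dialect corpus files, result tables and coloured HTML renderings.

The corpus dialect mirrors the public CHEMDNER distribution: UTF-8,
tab-separated, one record per line.  An *abstracts* file carries
``doc_id<TAB>title<TAB>abstract``; an *annotations* file carries
``doc_id<TAB>section<TAB>start<TAB>end<TAB>surface<TAB>type`` where section is
``T`` (title) or ``A`` (abstract) and offsets are 0-based, half-open,
counted in Unicode code points, per section.  Tabs/newlines inside text are
backslash-escaped on disk so that read(write(x)) == x.
"""

from __future__ import annotations

import csv
import html
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .extraction import ExtractedEntity


class CorpusFormatError(ValueError):
    """A structurally invalid corpus file.

    Carries enough context (path, line number, document id) for a one-line
    diagnostic.
    """

    def __init__(self, message: str, *, path=None, line: int | None = None,
                 doc_id: str | None = None):
        parts = []
        if path is not None:
            parts.append(str(path))
        if line is not None:
            parts.append(f"line {line}")
        if doc_id is not None:
            parts.append(f"document {doc_id!r}")
        prefix = " ".join(parts)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.path = path
        self.line = line
        self.doc_id = doc_id


class Section(Enum):
    """Which part of the abstract record an offset refers to."""

    TITLE = "T"
    ABSTRACT = "A"

    @classmethod
    def from_code(cls, code: str) -> "Section":
        try:
            return cls(code)
        except ValueError:
            raise CorpusFormatError(f"unknown section code {code!r}") from None


class EntityType(Enum):
    """Annotation types of the CHEMDNER scheme."""

    ABBREVIATION = "ABBREVIATION"
    FAMILY = "FAMILY"
    FORMULA = "FORMULA"
    IDENTIFIER = "IDENTIFIER"
    MULTIPLE = "MULTIPLE"
    SYSTEMATIC = "SYSTEMATIC"
    TRIVIAL = "TRIVIAL"
    NO_CLASS = "NO_CLASS"

    @classmethod
    def from_string(cls, s: str) -> "EntityType":
        key = s.strip().upper().replace(" ", "_")
        try:
            return cls(key)
        except ValueError:
            raise CorpusFormatError(f"unknown entity type {s!r}") from None


class ClassLabel(Enum):
    """Classification labels: five chemical base types, their union CNE,
    and the background class NON_CNE."""

    ABBREVIATION = "ABBREVIATION"
    SYSTEMATIC = "SYSTEMATIC"
    FORMULA = "FORMULA"
    FAMILY = "FAMILY"
    TRIVIAL = "TRIVIAL"
    CNE = "CNE"
    NON_CNE = "NON_CNE"


#: The five named chemical types (everything but the union label and background).
BASE_CLASSES: tuple[ClassLabel, ...] = (
    ClassLabel.ABBREVIATION,
    ClassLabel.SYSTEMATIC,
    ClassLabel.FORMULA,
    ClassLabel.FAMILY,
    ClassLabel.TRIVIAL,
)

_ETYPE_TO_LABEL = {
    EntityType.ABBREVIATION: ClassLabel.ABBREVIATION,
    EntityType.SYSTEMATIC: ClassLabel.SYSTEMATIC,
    EntityType.FORMULA: ClassLabel.FORMULA,
    EntityType.FAMILY: ClassLabel.FAMILY,
    EntityType.TRIVIAL: ClassLabel.TRIVIAL,
    # Types outside the five named ones are treated as background unless the
    # caller remaps them; the classifier trains on five named types + non-CNE.
    EntityType.IDENTIFIER: ClassLabel.NON_CNE,
    EntityType.MULTIPLE: ClassLabel.NON_CNE,
    EntityType.NO_CLASS: ClassLabel.NON_CNE,
}


def label_for_etype(etype: EntityType,
                    overrides: dict[EntityType, ClassLabel] | None = None) -> ClassLabel:
    """Map an annotation type to its training label (extra types -> NON_CNE)."""
    if overrides and etype in overrides:
        return overrides[etype]
    return _ETYPE_TO_LABEL[etype]


@dataclass(frozen=True)
class EntitySpan:
    """A labelled entity occurrence: half-open character offsets in a section."""

    section: Section
    start: int
    end: int
    surface: str
    etype: EntityType

    def check_against(self, text: str, *, doc_id: str = "?") -> None:
        if not (0 <= self.start < self.end <= len(text)):
            raise CorpusFormatError(
                f"span [{self.start}, {self.end}) outside section of length {len(text)}",
                doc_id=doc_id)
        found = text[self.start:self.end]
        if found != self.surface:
            raise CorpusFormatError(
                f"surface mismatch at [{self.start}, {self.end}): "
                f"annotation {self.surface!r} vs text {found!r}", doc_id=doc_id)


@dataclass
class AnnotatedDocument:
    """One abstract record: identifier, title and abstract text, entity spans."""

    doc_id: str
    title: str
    abstract: str
    spans: list[EntitySpan] = field(default_factory=list)

    def section_text(self, section: Section) -> str:
        return self.title if section is Section.TITLE else self.abstract

    def section_spans(self, section: Section) -> list[EntitySpan]:
        return [s for s in self.spans if s.section is section]

    def validate(self) -> None:
        if not self.doc_id:
            raise CorpusFormatError("empty document id")
        for span in self.spans:
            span.check_against(self.section_text(span.section), doc_id=self.doc_id)


# ---------------------------------------------------------------------------
# TSV escaping: the on-disk dialect is line/tab structured, so tabs, newlines
# and backslashes inside text fields are escaped.

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}
# Everything str.splitlines treats as a line boundary must be escaped, or a
# stray form feed would shift every later record by one line.
_OTHER_BREAKS = "\v\f\x1c\x1d\x1e\x85\u2028\u2029"
_UNESCAPES = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}


def _escape(text: str) -> str:
    out = []
    for ch in text:
        if ch in _ESCAPES:
            out.append(_ESCAPES[ch])
        elif ch in _OTHER_BREAKS:
            out.append(f"\\u{ord(ch):04x}")
        else:
            out.append(ch)
    return "".join(out)


def _unescape(text: str) -> str:
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            if nxt in _UNESCAPES:
                out.append(_UNESCAPES[nxt])
                i += 2
                continue
            if nxt == "u" and i + 6 <= len(text):
                out.append(chr(int(text[i + 2:i + 6], 16)))
                i += 6
                continue
        out.append(ch)
        i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# Readers / writers


def read_abstracts(path) -> list[AnnotatedDocument]:
    """Read an abstracts TSV: one ``doc_id, title, abstract`` record per line.

    Raises :class:`CorpusFormatError` (with the line number) on malformed
    lines; an empty file yields an empty list.
    """
    docs: list[AnnotatedDocument] = []
    seen: set[str] = set()
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise CorpusFormatError(
                f"expected 3 tab-separated fields, got {len(fields)}",
                path=path, line=lineno)
        doc_id = fields[0]
        if not doc_id:
            raise CorpusFormatError("empty document id", path=path, line=lineno)
        if doc_id in seen:
            raise CorpusFormatError(f"duplicate document id {doc_id!r}",
                                    path=path, line=lineno)
        seen.add(doc_id)
        docs.append(AnnotatedDocument(doc_id, _unescape(fields[1]),
                                      _unescape(fields[2])))
    return docs


def write_abstracts(docs: Sequence[AnnotatedDocument], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(f"{doc.doc_id}\t{_escape(doc.title)}\t{_escape(doc.abstract)}\n")


def read_annotations(path, documents: Sequence[AnnotatedDocument]
                     ) -> list[AnnotatedDocument]:
    """Attach annotation spans to their documents, verifying every offset.

    Each attached span is checked against the referenced section text; a
    mismatch raises :class:`CorpusFormatError` naming the document and the
    offsets.  Returns the same document objects with spans attached, sorted
    by (section, start).
    """
    by_id = {doc.doc_id: doc for doc in documents}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise CorpusFormatError(
                f"expected 6 tab-separated fields, got {len(fields)}",
                path=path, line=lineno)
        doc_id, sec_code, start_s, end_s, surface, etype_s = fields
        if doc_id not in by_id:
            raise CorpusFormatError(f"unknown document id {doc_id!r}",
                                    path=path, line=lineno)
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise CorpusFormatError(
                f"non-integer offsets {start_s!r}, {end_s!r}",
                path=path, line=lineno, doc_id=doc_id) from None
        try:
            section = Section.from_code(sec_code)
            etype = EntityType.from_string(etype_s)
            span = EntitySpan(section, start, end, _unescape(surface), etype)
            span.check_against(by_id[doc_id].section_text(section), doc_id=doc_id)
        except CorpusFormatError as err:
            raise CorpusFormatError(str(err), path=path, line=lineno) from None
        by_id[doc_id].spans.append(span)
    for doc in documents:
        doc.spans.sort(key=lambda s: (s.section.value, s.start, s.end))
    return list(documents)


def write_annotations(docs: Sequence[AnnotatedDocument], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            for s in sorted(doc.spans, key=lambda s: (s.section.value, s.start, s.end)):
                fh.write(f"{doc.doc_id}\t{s.section.value}\t{s.start}\t{s.end}\t"
                         f"{_escape(s.surface)}\t{s.etype.value}\n")


_EXTRACTION_HEADER = ["doc_id", "section", "start", "end", "surface", "score"]


def write_extraction_table(entities: Iterable["ExtractedEntity"], path) -> None:
    """Write extracted entities as CSV, ordered by (doc_id, section, start)."""
    rows = sorted(entities, key=lambda e: (e.doc_id, e.section.value, e.start))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EXTRACTION_HEADER)
        for e in rows:
            writer.writerow([e.doc_id, e.section.value, e.start, e.end,
                             e.surface, repr(e.score)])


def read_extraction_table(path) -> list["ExtractedEntity"]:
    from .extraction import ExtractedEntity

    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _EXTRACTION_HEADER:
            raise CorpusFormatError(f"unexpected header {header!r}", path=path)
        for row in reader:
            doc_id, sec, start, end, surface, score = row
            out.append(ExtractedEntity(doc_id, Section.from_code(sec),
                                       int(start), int(end), surface, float(score)))
    return out


# ---------------------------------------------------------------------------
# Coloured HTML rendering

#: Anchor colours: light green = confidently chemical (Pc=1), light red =
#: confidently background (Pnc=1), blue = no evidence either way (Pc=Pnc=0).
COLOR_CNE = (0x90, 0xEE, 0x90)
COLOR_NON_CNE = (0xF0, 0x80, 0x80)
COLOR_UNKNOWN = (0x00, 0x00, 0xFF)


def blend_color(pc: float, pnc: float) -> str:
    """Barycentric blend of the three anchors, weights (Pc, Pnc, 1-max(Pc,Pnc))."""
    if not (0.0 <= pc <= 1.0 and 0.0 <= pnc <= 1.0):
        raise ValueError(f"probabilities outside [0, 1]: pc={pc}, pnc={pnc}")
    wb = 1.0 - max(pc, pnc)
    total = pc + pnc + wb
    rgb = tuple(
        round((pc * g + pnc * r + wb * b) / total)
        for g, r, b in zip(COLOR_CNE, COLOR_NON_CNE, COLOR_UNKNOWN)
    )
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def render_colored_html(text: str,
                        char_scores: Sequence[tuple[float, float]]) -> str:
    """Render text with one (Pc, Pnc) pair per character as standalone HTML.

    Stripping the tags (and unescaping entities) recovers the input exactly;
    runs of equal colour are merged into a single span.
    """
    if len(char_scores) != len(text):
        raise ValueError(
            f"{len(char_scores)} score pairs for {len(text)} characters")
    pieces = []
    run_start = 0
    for i in range(1, len(text) + 1):
        if i == len(text) or blend_color(*char_scores[i]) != blend_color(*char_scores[run_start]):
            color = blend_color(*char_scores[run_start])
            chunk = html.escape(text[run_start:i])
            pieces.append(f'<span style="background-color:{color}">{chunk}</span>')
            run_start = i
    body = "".join(pieces)
    return ('<!DOCTYPE html><html><head><meta charset="utf-8"/>'
            '<style>pre{font-family:monospace;white-space:pre-wrap}</style>'
            f'</head><body><pre>{body}</pre></body></html>')
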