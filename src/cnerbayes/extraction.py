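"""Whole-entity extraction from per-token predictions.

Tokens whose score (Pc - Pnc) is strictly above the threshold T and which
survive the token-level exclusion filters are grouped into maximal runs of
consecutive tokens; each run becomes one candidate entity whose surface is
the original document text from the first token's start to the last token's
end (so inter-token punctuation and whitespace are preserved).  Entity-level
filters then remove whole candidates.

Filters exist because a few token shapes are overrepresented in training and
score high without being chemical mentions — bare numbers, lone punctuation,
and high-frequency words that are (nearly) never entity targets.  The default
token rules exclude purely numeric and punctuation-only tokens; the
:func:`overrepresented_surface_filter` adds a training-derived stop list.
Default entity rules drop candidates with broken encoding, unbalanced
brackets, or a single non-alphanumeric character.  All rules are plain data
and can be replaced by a user-supplied configuration.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

from .corpus import Section
from .tokens import Token

TOKEN_LEVEL = "token"
ENTITY_LEVEL = "entity"

_BRACKETS = {"(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


@dataclass(frozen=True)
class ExtractedEntity:
    """One extracted chemical named entity (offsets into the section text)."""

    doc_id: str
    section: Section
    start: int
    end: int
    surface: str
    score: float


@dataclass(frozen=True)
class FilterRule:
    """A named exclusion rule; ``matches(text)`` True means *exclude*."""

    name: str
    kind: str  # TOKEN_LEVEL or ENTITY_LEVEL
    matches: Callable[[str], bool]
    pattern: str | None = None  # source regex, when the rule is regex-based


def regex_rule(name: str, kind: str, pattern: str) -> FilterRule:
    compiled = re.compile(pattern)
    return FilterRule(name, kind, lambda s: compiled.fullmatch(s) is not None,
                      pattern)


def _has_bad_encoding(text: str) -> bool:
    return any(ch == "�" or unicodedata.category(ch) in ("Cc", "Cf")
               for ch in text)


def _has_unbalanced_brackets(text: str) -> bool:
    stack: list[str] = []
    for ch in text:
        if ch in _BRACKETS:
            stack.append(ch)
        elif ch in _CLOSERS:
            if not stack or stack.pop() != _CLOSERS[ch]:
                return True
    return bool(stack)


def default_token_filters() -> list[FilterRule]:
    """Numeric tokens and punctuation-only tokens (including lone brackets)."""
    return [
        regex_rule("numeric", TOKEN_LEVEL, r"[+-]?\d+(?:[.,]\d+)*"),
        regex_rule("punctuation", TOKEN_LEVEL, r"[^\w\s]+"),
    ]


def default_entity_filters() -> list[FilterRule]:
    return [
        FilterRule("bad_encoding", ENTITY_LEVEL, _has_bad_encoding),
        FilterRule("unbalanced_brackets", ENTITY_LEVEL, _has_unbalanced_brackets),
        FilterRule("stray_single_char", ENTITY_LEVEL,
                   lambda s: len(s) == 1 and not s.isalnum()),
    ]


def overrepresented_surface_filter(surface_stats: dict[str, list[int]],
                                   min_count: int = 10,
                                   max_cne_fraction: float = 0.05) -> FilterRule:
    """Exclude token surfaces that training shows are frequent non-entities.

    A surface is excluded when it occurred at least ``min_count`` times as a
    training target and was an entity in at most ``max_cne_fraction`` of those
    occurrences.  This is the data-driven counterpart of a hand-written stop
    list: frequent function words pick up high scores purely by sitting next
    to entities, and this rule removes them from extraction candidacy.
    """
    stop = {surface for surface, (count, cne) in surface_stats.items()
            if count >= min_count and cne <= max_cne_fraction * count}

    return FilterRule("overrepresented_non_entity", TOKEN_LEVEL,
                      lambda s: s.casefold() in stop)


def apply_filters(text: str, rules: Sequence[FilterRule]) -> bool:
    """True when the candidate survives (is excluded by no rule)."""
    return not any(rule.matches(text) for rule in rules)


def extract_entities(doc_id: str, text: str, tokens: Sequence[Token],
                     token_scores: Sequence[tuple[float, float]],
                     threshold: float = 0.3,
                     token_filters: Sequence[FilterRule] = (),
                     entity_filters: Sequence[FilterRule] = ()
                     ) -> list[ExtractedEntity]:
    """Threshold, filter and concatenate per-token scores into entities.

    ``token_scores`` holds one (Pc, Pnc) pair per token.  A token is a
    candidate iff Pc - Pnc > threshold (strictly) and it passes every
    token-level rule; maximal runs of consecutive candidate tokens become
    entities scored by the mean (Pc - Pnc) of their members.
    """
    if len(tokens) != len(token_scores):
        raise ValueError(f"{len(token_scores)} score pairs for "
                         f"{len(tokens)} tokens")
    token_rules = [r for r in token_filters if r.kind == TOKEN_LEVEL]
    entity_rules = [r for r in entity_filters if r.kind == ENTITY_LEVEL]

    candidates = [
        i for i, (tok, (pc, pnc)) in enumerate(zip(tokens, token_scores))
        if pc - pnc > threshold and apply_filters(tok.surface, token_rules)
    ]
    entities: list[ExtractedEntity] = []
    run: list[int] = []
    for idx in candidates + [None]:  # sentinel flushes the last run
        if run and (idx is None or idx != run[-1] + 1):
            first, last = tokens[run[0]], tokens[run[-1]]
            surface = text[first.start:last.end]
            score = sum(token_scores[i][0] - token_scores[i][1]
                        for i in run) / len(run)
            if apply_filters(surface, entity_rules):
                entities.append(ExtractedEntity(
                    doc_id, first.section, first.start, last.end, surface,
                    score))
            run = []
        if idx is not None:
            run.append(idx)
    return entities


def score_tokens(text: str, results, calibration,
                 section: Section = Section.ABSTRACT,
                 window: int | None = None) -> tuple[list[Token],
                                                     list[tuple[float, float]]]:
    """Tokenize a text and predict (Pc, Pnc) for every token."""
    from .tokens import build_fots, tokenize

    tokens = tokenize(text, section)
    window = results.window if window is None else window
    fots = build_fots(tokens, [], window)
    scores = []
    for fot in fots:
        pred = results.predict_fot(fot, calibration)
        scores.append((pred.pc, pred.pnc))
    return tokens, scores


def extract_from_text(doc_id: str, text: str, results, calibration,
                      threshold: float = 0.3,
                      token_filters: Sequence[FilterRule] | None = None,
                      entity_filters: Sequence[FilterRule] | None = None,
                      section: Section = Section.ABSTRACT
                      ) -> list[ExtractedEntity]:
    """Convenience path: score a raw text and extract entities from it."""
    if token_filters is None:
        token_filters = default_token_filters()
        if results.surface_stats:
            token_filters = token_filters + [
                overrepresented_surface_filter(results.surface_stats)]
    if entity_filters is None:
        entity_filters = default_entity_filters()
    tokens, scores = score_tokens(text, results, calibration, section)
    return extract_entities(doc_id, text, tokens, scores, threshold,
                            token_filters, entity_filters)


# ---------------------------------------------------------------------------
# Filter configuration files: one rule per line,
#   token <name> regex:<pattern>        entity <name> builtin:<builtin-name>

_BUILTINS: dict[str, Callable[[str], bool]] = {
    "bad_encoding": _has_bad_encoding,
    "unbalanced_brackets": _has_unbalanced_brackets,
    "stray_single_char": lambda s: len(s) == 1 and not s.isalnum(),
}


def load_filter_config(path) -> list[FilterRule]:
    rules: list[FilterRule] = []
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            kind, name, spec = line.split(None, 2)
        except ValueError:
            raise ValueError(f"{path} line {lineno}: expected "
                             f"'<kind> <name> <spec>'") from None
        if kind not in (TOKEN_LEVEL, ENTITY_LEVEL):
            raise ValueError(f"{path} line {lineno}: unknown kind {kind!r}")
        if spec.startswith("regex:"):
            rules.append(regex_rule(name, kind, spec[len("regex:"):]))
        elif spec.startswith("builtin:"):
            builtin = spec[len("builtin:"):]
            if builtin not in _BUILTINS:
                raise ValueError(f"{path} line {lineno}: unknown builtin "
                                 f"{builtin!r}")
            rules.append(FilterRule(name, kind, _BUILTINS[builtin]))
        else:
            raise ValueError(f"{path} line {lineno}: spec must start with "
                             f"'regex:' or 'builtin:'")
    return rules


def write_default_filter_config(path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# token/entity exclusion rules\n")
        fh.write(r"token numeric regex:[+-]?\d+(?:[.,]\d+)*" + "\n")
        fh.write(r"token punctuation regex:[^\w\s]+" + "\n")
        fh.write("entity bad_encoding builtin:bad_encoding\n")
        fh.write("entity unbalanced_brackets builtin:unbalanced_brackets\n")
        fh.write("entity stray_single_char builtin:stray_single_char\n")
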