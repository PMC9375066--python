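"""Multi-n-gram descriptor sets.

A descriptor is an uppercased contiguous character substring of a token, of
length 1..n_max (default 5).  A FoT's descriptor set is the union over its
member tokens; grams never span token boundaries and carry set (not multiset)
semantics, so a repeated substring counts once.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .corpus import ClassLabel, Section
from .tokens import FoT

#: Default maximal gram length — the accuracy/complexity optimum for this
#: classifier (longer grams become nearly unique in the training set).
DEFAULT_N_MAX = 5


def token_ngrams(token: str, n_max: int = DEFAULT_N_MAX) -> frozenset[str]:
    """All distinct uppercased substrings of length 1..min(n_max, len(token))."""
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    t = token.upper()
    length = len(t)
    return frozenset(t[i:i + n]
                     for n in range(1, min(n_max, length) + 1)
                     for i in range(length - n + 1))


def position_ngrams(token: str, index: int,
                    n_max: int = DEFAULT_N_MAX) -> frozenset[str]:
    """All grams of length 1..n_max whose character interval covers ``index``.

    This is the per-character descriptor set used for letter-level scoring
    and colouring; it is always a subset of :func:`token_ngrams`.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    if not (0 <= index < len(token)):
        raise IndexError(f"index {index} outside token of length {len(token)}")
    t = token.upper()
    length = len(t)
    grams = set()
    for n in range(1, min(n_max, length) + 1):
        for start in range(max(0, index - n + 1), min(index, length - n) + 1):
            grams.add(t[start:start + n])
    return frozenset(grams)


def fot_descriptors(fot: FoT, n_max: int = DEFAULT_N_MAX) -> frozenset[str]:
    """Union of per-token gram sets over target and context tokens."""
    grams: set[str] = set()
    for token in fot.tokens:
        grams |= token_ngrams(token.surface, n_max)
    return frozenset(grams)


# ---------------------------------------------------------------------------
# Plain-text persistence of descriptor sets, for inspection and fixtures:
# doc_id <TAB> section <TAB> start <TAB> end <TAB> label <TAB> grams...

def write_descriptor_sets(fots: Iterable[FoT], path,
                          n_max: int = DEFAULT_N_MAX) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fot in fots:
            grams = " ".join(sorted(fot_descriptors(fot, n_max)))
            t = fot.target
            fh.write(f"{fot.doc_id}\t{t.section.value}\t{t.start}\t{t.end}\t"
                     f"{fot.label.value}\t{grams}\n")


def read_descriptor_sets(path) -> list[tuple[str, Section, int, int,
                                             ClassLabel, frozenset[str]]]:
    """Read back records written by :func:`write_descriptor_sets`."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line:
            continue
        doc_id, sec, start, end, label, grams = line.split("\t")
        out.append((doc_id, Section(sec), int(start), int(end),
                    ClassLabel(label),
                    frozenset(grams.split(" ")) if grams else frozenset()))
    return out
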