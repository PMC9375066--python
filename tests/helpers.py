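"""Independent oracles and micro-corpus builders shared by the test suite.

The brute-force scorer here recomputes priors, conditionals, centred arcsine
mean, sine and the Möbius ratio from scratch in plain Python over
(label, gram-set) pairs; it shares no code with the package implementation.
"""

from __future__ import annotations

import math
import random

from cnerbayes import ClassLabel, FoT, Section, Token
from cnerbayes.model import CLASS_ORDER

BASE = [ClassLabel.ABBREVIATION, ClassLabel.SYSTEMATIC, ClassLabel.FORMULA,
        ClassLabel.FAMILY, ClassLabel.TRIVIAL]


def brute_force_b(training: list[tuple[ClassLabel, frozenset]],
                  query_grams: frozenset, label: ClassLabel,
                  sum_mode: str = "mean") -> float:
    """Independent B-statistic: direct counting + arcsine arithmetic."""
    n_total = len(training)

    def in_class(lab: ClassLabel, k: ClassLabel) -> bool:
        if k is ClassLabel.CNE:
            return lab is not ClassLabel.NON_CNE
        return lab is k

    nk = sum(1 for lab, _ in training if in_class(lab, label))
    s0 = 2.0 * nk / n_total - 1.0
    if abs(s0) >= 1.0:
        return 0.0
    a0 = math.asin(s0)
    terms = []
    for gram in sorted(query_grams):
        ni = sum(1 for _, grams in training if gram in grams)
        if ni == 0:
            continue  # uninformative: contributes the prior, i.e. zero
        nik = sum(1 for lab, grams in training
                  if gram in grams and in_class(lab, label))
        cond = nik / ni
        terms.append(math.asin(2.0 * cond - 1.0) - a0)
    if not terms:
        agg = 0.0
    elif sum_mode == "mean":
        agg = sum(terms) / len(terms)
    else:
        agg = sum(terms)
    s = math.sin(a0 + agg)
    denom = 1.0 - s * s0
    if denom == 0.0:
        return 0.0
    return max(-1.0, min(1.0, (s - s0) / denom))


def make_token(surface: str, start: int = 0,
               section: Section = Section.ABSTRACT) -> Token:
    return Token(surface, start, start + len(surface), section)


def fot_from_words(words: list[str], label: ClassLabel,
                   window: int | None = None, doc_id: str = "T") -> FoT:
    """Single-target FoT whose context is the remaining words, in order.

    The target is the middle word; offsets are laid out left to right.
    """
    tokens = []
    pos = 0
    for w in words:
        tokens.append(make_token(w, pos))
        pos += len(w) + 1
    mid = len(words) // 2
    w = max(mid, len(words) - 1 - mid) if window is None else window
    return FoT(tokens[mid], tuple(tokens[:mid]), tuple(tokens[mid + 1:]),
               min(w, 3), label, doc_id)


_ALPHABET = "abcdefg"


def random_micro_corpus(rng: random.Random, max_fots: int = 50,
                        max_word_len: int = 5
                        ) -> tuple[list[FoT], list[tuple[ClassLabel, frozenset]]]:
    """A random small corpus as (FoT list, independent (label, grams) view).

    Gram sets are produced independently of the package (plain substring
    enumeration) so the oracle's view does not share the implementation's
    feature code.
    """
    from itertools import combinations

    labels = [ClassLabel.TRIVIAL, ClassLabel.SYSTEMATIC, ClassLabel.NON_CNE]
    n = rng.randint(4, max_fots)
    fots, view = [], []
    for i in range(n):
        word = "".join(rng.choice(_ALPHABET)
                       for _ in range(rng.randint(1, max_word_len)))
        label = rng.choice(labels)
        fots.append(FoT(make_token(word, 0), (), (), 0, label, f"D{i}"))
        grams = {word[a:b].upper()
                 for a in range(len(word)) for b in range(a + 1, len(word) + 1)
                 if b - a <= 2}
        view.append((label, frozenset(grams)))
    return fots, view


def rank_auc(pos, neg) -> float:
    """Mid-rank AUC via explicit pair enumeration (O(n^2) oracle)."""
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
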