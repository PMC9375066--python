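"""Seeded generator of CHEMDNER-format corpora with known entity spans.

The generator emulates the statistical structure this classifier relies on
in real abstracts, without pretending to be English prose:

* background text is drawn from a fixed vocabulary of common words, grouped
  into sentences with commas and full stops, so punctuation tokens occur in
  ordinary (non-chemical) contexts too;
* chemical mentions follow per-class grammars (systematic morpheme chains,
  element/digit formulas, uppercase abbreviations, family suffixes, a fixed
  trivial-name lexicon) so their character n-gram distribution is distinct
  from the background;
* mentions appear in the local idioms chemical text actually uses —
  multi-word systematic names ("dimethylhexane anhydride"), family phrases
  ("phenolic flavonoids"), drug salts ("chloroquine phosphate"),
  parenthesised abbreviations/formulas ("(MTX)"), comma-separated lists
  ("quercetin, rutin, curcumin") — plus a small residue of bare single-word
  mentions and punctuated locant names ("1,2-dimethylhexane").  The idioms
  matter: with a symmetric context window the classifier can only separate a
  token from its neighbours through descriptor-set composition, which these
  idioms shape the way real chemistry prose does.

Class weights default to the relative class sizes of a large expert-annotated
corpus (heavy imbalance, merged-CNE prior about 1:15); the entity rate is the
expected fraction of *tokens* lying inside gold spans.  Generation is fully
deterministic for a given seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

from .corpus import (AnnotatedDocument, ClassLabel, EntitySpan, EntityType,
                     Section, write_abstracts, write_annotations)
from .tokens import build_fots, tokenize

# Relative class sizes of the annotated training corpus the defaults emulate.
_CLASS_SIZES = {
    ClassLabel.ABBREVIATION: 12506,
    ClassLabel.FORMULA: 13466,
    ClassLabel.FAMILY: 19017,
    ClassLabel.SYSTEMATIC: 32510,
    ClassLabel.TRIVIAL: 25140,
}
_TOTAL = sum(_CLASS_SIZES.values())
DEFAULT_CLASS_MIX = {k: v / _TOTAL for k, v in _CLASS_SIZES.items()}

_LABEL_TO_ETYPE = {
    ClassLabel.ABBREVIATION: EntityType.ABBREVIATION,
    ClassLabel.SYSTEMATIC: EntityType.SYSTEMATIC,
    ClassLabel.FORMULA: EntityType.FORMULA,
    ClassLabel.FAMILY: EntityType.FAMILY,
    ClassLabel.TRIVIAL: EntityType.TRIVIAL,
}


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the corpus generator (defaults are the reference condition)."""

    n_docs: int = 200
    tokens_per_doc: tuple[int, int] = (40, 80)   # word slots in the abstract
    title_words: tuple[int, int] = (4, 8)
    entity_rate: float = 0.06                    # fraction of tokens in spans
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    seed: int = 42

    def validate(self) -> None:
        if self.n_docs <= 0:
            raise ValueError("n_docs must be positive")
        if not (0.0 < self.entity_rate < 1.0):
            raise ValueError("entity_rate must lie in (0, 1)")
        lo, hi = self.tokens_per_doc
        if not (0 < lo <= hi):
            raise ValueError("tokens_per_doc range must be positive and ordered")
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_mix weights must sum to 1, got {total}")
        if any(w < 0 for w in self.class_mix.values()):
            raise ValueError("class_mix weights must be non-negative")


# ---------------------------------------------------------------------------
# Vocabulary

BACKGROUND_WORDS = (
    "the of and in to for with was were are is on by from that this these "
    "results study analysis data effect effects observed showed significant "
    "increase decrease treatment control group groups patients cells cell "
    "levels level activity response dose doses exposure method methods using "
    "based compared values value mean total number present performed found "
    "obtained reported associated related important role potential possible "
    "clinical experimental conditions condition model models system time "
    "after before during between within among both several various different "
    "higher lower high low samples sample tissue serum plasma blood liver "
    "brain protein proteins gene genes expression receptor receptors enzyme "
    "enzymes pathway pathways mechanism mechanisms function functions binding "
    "concentration concentrations measured determined evaluated investigated "
    "assessed examined tested applied developed proposed approach approaches "
    "species animals rats mice human humans adult male female age weight "
    "days weeks hours minutes min however therefore moreover furthermore "
    "although whereas while when where which whose there here also only "
    "more most less least very well may might could should would can not"
).split()

SYSTEMATIC_PREFIXES = (
    "meth eth prop but pent hex hept oct cyclo chloro fluoro bromo iodo "
    "hydroxy amino nitro oxo thio phenyl benzyl benzo di tri tetra sulfo "
    "carboxy acetyl methoxy ethoxy"
).split()
SYSTEMATIC_SUFFIXES = (
    "ane ene yne ol one al ylene amine anoate oxide ylate anol anone"
).split()
SYSTEMATIC_SECOND_WORDS = "acid ester anhydride amide chloride oxide".split()
LOCANT_PREFIXES = ("1,2-", "2-", "1,3-", "3,4-", "N-", "2,6-", "4-")

ELEMENTS = "C H N O S P Cl Na K Fe Mg Ca Zn Cu".split()

FAMILY_STEMS = (
    "flavon terpen saponin quinolin indol phenol steroid carotenoid alkal "
    "glycos coumarin anthocyan tann lignan"
).split()
FAMILY_SUFFIXES = "oids ines ols ates osides ides anes".split()
FAMILY_ADJECTIVES = (
    "phenolic glycosylated substituted halogenated polycyclic sulfonated "
    "aromatic heterocyclic"
).split()

TRIVIAL_NAMES = (
    "haloperidol quercetin curcumin chloroquine hydroxychloroquine rutin "
    "darunavir saquinavir morphine caffeine aspirin menthol dithizone "
    "tangeretin myricetin luteolin apigenin kaempferol berberine resveratrol "
    "capsaicin nicotine atropine colchicine"
).split()
SALT_WORDS = (
    "phosphate sulfate hydrochloride acetate decanoate dihydrate maleate "
    "citrate tartrate"
).split()

# Local idioms per class: (idiom name, probability).  "plain" mentions are the
# designed-in hard case (a bare word between two ordinary words); the other
# idioms reproduce the punctuation/phrase structure that makes real chemical
# mentions separable from their neighbours.
IDIOMS: dict[ClassLabel, tuple[tuple[str, float], ...]] = {
    ClassLabel.ABBREVIATION: (("paren", 0.96), ("plain", 0.04)),
    ClassLabel.FORMULA: (("paren", 0.64), ("list", 0.32), ("plain", 0.04)),
    ClassLabel.FAMILY: (("twoword", 0.66), ("list", 0.30), ("plain", 0.04)),
    ClassLabel.SYSTEMATIC: (("twoword", 0.62), ("list", 0.29),
                            ("locant", 0.05), ("plain", 0.04)),
    ClassLabel.TRIVIAL: (("salt", 0.54), ("list", 0.42), ("plain", 0.04)),
}

_COMMA_PROB = 0.06     # comma attached after a background word
_SENTENCE_LEN = (8, 14)  # background words per sentence


# ---------------------------------------------------------------------------
# Surface grammars


def _systematic_word(rng: random.Random) -> str:
    n = rng.randint(2, 4)
    parts = [rng.choice(SYSTEMATIC_PREFIXES) for _ in range(n)]
    return "".join(parts) + rng.choice(SYSTEMATIC_SUFFIXES)


def _formula(rng: random.Random) -> str:
    n = rng.randint(2, 4)
    return "".join(rng.choice(ELEMENTS) + str(rng.randint(1, 12))
                   for _ in range(n))


def _abbreviation(rng: random.Random) -> str:
    return "".join(rng.choice("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
                   for _ in range(rng.randint(2, 4)))


def _family_word(rng: random.Random) -> str:
    return rng.choice(FAMILY_STEMS) + rng.choice(FAMILY_SUFFIXES)


def _entity_surface(rng: random.Random, label: ClassLabel, idiom: str) -> str:
    if label is ClassLabel.SYSTEMATIC:
        if idiom == "twoword":
            return f"{_systematic_word(rng)} {rng.choice(SYSTEMATIC_SECOND_WORDS)}"
        if idiom == "locant":
            return rng.choice(LOCANT_PREFIXES) + _systematic_word(rng)
        return _systematic_word(rng)
    if label is ClassLabel.FORMULA:
        return _formula(rng)
    if label is ClassLabel.ABBREVIATION:
        return _abbreviation(rng)
    if label is ClassLabel.FAMILY:
        if idiom == "twoword":
            return f"{rng.choice(FAMILY_ADJECTIVES)} {_family_word(rng)}"
        return _family_word(rng)
    if label is ClassLabel.TRIVIAL:
        if idiom == "salt":
            return f"{rng.choice(TRIVIAL_NAMES)} {rng.choice(SALT_WORDS)}"
        return rng.choice(TRIVIAL_NAMES)
    raise ValueError(f"not an entity class: {label}")


def _choose(rng: random.Random, table) -> str:
    r = rng.random()
    acc = 0.0
    for item, weight in table:
        acc += weight
        if r < acc:
            return item
    return table[-1][0]


# ---------------------------------------------------------------------------
# Section assembly


class _SectionBuilder:
    """Accumulates text and records entity spans at exact offsets."""

    def __init__(self, section: Section):
        self.section = section
        self.parts: list[str] = []
        self.length = 0
        self.spans: list[EntitySpan] = []

    def _append(self, text: str) -> int:
        start = self.length
        self.parts.append(text)
        self.length += len(text)
        return start

    def sep(self) -> None:
        if self.length:
            self._append(" ")

    def word(self, w: str) -> None:
        self.sep()
        self._append(w)

    def attach(self, s: str) -> None:
        self._append(s)

    def entity(self, surface: str, label: ClassLabel, *, sep: bool = True) -> None:
        if sep:
            self.sep()
        start = self._append(surface)
        self.spans.append(EntitySpan(self.section, start, start + len(surface),
                                     surface, _LABEL_TO_ETYPE[label]))

    def text(self) -> str:
        return "".join(self.parts)


def _emit_entity_event(rng: random.Random, builder: _SectionBuilder,
                       label: ClassLabel) -> int:
    """Emit one mention event (possibly a list); returns word slots consumed."""
    idiom = _choose(rng, IDIOMS[label])
    if idiom == "list":
        n = rng.randint(3, 4)
        for j in range(n):
            surface = _entity_surface(rng, label, "plain")
            builder.entity(surface, label)
            if j < n - 1:
                builder.attach(",")
        return n
    if idiom == "paren":
        surface = _entity_surface(rng, label, "plain")
        builder.sep()
        builder.attach("(")
        builder.entity(surface, label, sep=False)
        builder.attach(")")
        return 1
    surface = _entity_surface(rng, label, idiom)
    builder.entity(surface, label)
    return len(surface.split(" "))


def _expected_event_tokens(params: GeneratorParams, probe_seed: int,
                           n_probe: int = 400) -> float:
    """Monte-Carlo estimate of entity tokens emitted per mention event."""
    rng = random.Random(probe_seed)
    labels = list(params.class_mix)
    weights = [params.class_mix[l] for l in labels]
    total = 0
    for _ in range(n_probe):
        label = rng.choices(labels, weights)[0]
        builder = _SectionBuilder(Section.ABSTRACT)
        _emit_entity_event(rng, builder, label)
        total += sum(len(tokenize(s.surface)) for s in builder.spans)
    return total / n_probe


def _emit_section(rng: random.Random, builder: _SectionBuilder,
                  n_slots: int, params: GeneratorParams,
                  p_event: float) -> None:
    labels = list(params.class_mix)
    weights = [params.class_mix[l] for l in labels]
    slots = 0
    words_in_sentence = 0
    sentence_target = rng.randint(*_SENTENCE_LEN)
    prev_was_entity = False
    while slots < n_slots:
        if not prev_was_entity and rng.random() < p_event:
            label = rng.choices(labels, weights)[0]
            slots += _emit_entity_event(rng, builder, label)
            prev_was_entity = True
            words_in_sentence += 1
            continue
        prev_was_entity = False
        builder.word(rng.choice(BACKGROUND_WORDS))
        slots += 1
        words_in_sentence += 1
        if rng.random() < _COMMA_PROB:
            builder.attach(",")
        if words_in_sentence >= sentence_target:
            builder.attach(".")
            words_in_sentence = 0
            sentence_target = rng.randint(*_SENTENCE_LEN)
    builder.attach(".")


def generate_corpus(params: GeneratorParams | None = None,
                    **overrides) -> list[AnnotatedDocument]:
    """Generate a labelled corpus; byte-identical for identical parameters."""
    params = replace(params or GeneratorParams(), **overrides)
    params.validate()
    rng = random.Random(params.seed)
    tau = _expected_event_tokens(params, probe_seed=params.seed ^ 0x5EED)
    # Solve p so that the expected token share inside entities matches
    # entity_rate: p*tau / (p*tau + (1-p)*tau_bg) = rate, with tau_bg the
    # tokens a background slot yields (word + attached punctuation).
    tau_bg = 1.0 + _COMMA_PROB + 1.0 / ((_SENTENCE_LEN[0] + _SENTENCE_LEN[1]) / 2)
    rate = params.entity_rate
    p_event = rate * tau_bg / (tau * (1.0 - rate) + rate * tau_bg)

    docs = []
    for i in range(params.n_docs):
        doc_id = f"SYN{i:05d}"
        title = _SectionBuilder(Section.TITLE)
        _emit_section(rng, title, rng.randint(*params.title_words), params,
                      p_event)
        abstract = _SectionBuilder(Section.ABSTRACT)
        _emit_section(rng, abstract, rng.randint(*params.tokens_per_doc),
                      params, p_event)
        doc = AnnotatedDocument(doc_id, title.text(), abstract.text(),
                                title.spans + abstract.spans)
        doc.validate()
        docs.append(doc)
    return docs


def write_corpus(corpus, out_prefix) -> tuple[str, str]:
    """Write the abstracts/annotations TSV pair; returns the two paths."""
    abstracts = f"{out_prefix}.abstracts.tsv"
    annotations = f"{out_prefix}.annotations.tsv"
    write_abstracts(corpus, abstracts)
    write_annotations(corpus, annotations)
    return abstracts, annotations


def corpus_stats(corpus) -> dict:
    """Token counts per class and the imbalance ratio R = N / Nk.

    Counts are per-token at window 0 (one fragment per token), mirroring the
    layout of per-class training-set summaries: N, per-class Nk, and R as a
    measure of imbalance (``None`` when a class is absent).
    """
    counts = {label: 0 for label in ClassLabel if label is not ClassLabel.CNE}
    total = 0
    for doc in corpus:
        for fot in document_fots_window0(doc):
            counts[fot.label] = counts.get(fot.label, 0) + 1
            total += 1
    cne = sum(v for k, v in counts.items() if k is not ClassLabel.NON_CNE)
    stats = {"N": total, "classes": {}}
    for label, nk in {**counts, ClassLabel.CNE: cne}.items():
        stats["classes"][label] = {
            "n": nk,
            "ratio": (total / nk) if nk else None,
        }
    return stats


def document_fots_window0(doc: AnnotatedDocument):
    for section in (Section.TITLE, Section.ABSTRACT):
        tokens = tokenize(doc.section_text(section), section)
        yield from build_fots(tokens, doc.section_spans(section), 0, doc.doc_id)
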