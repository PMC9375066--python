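# Methods

## Model

`cnerbayes` classifies each token of a text by the characters of its
*fragment of text* (FoT): the target token plus up to w neighbouring tokens
on each side (w ∈ {0..3}, default 1).  Title and abstract are tokenized
independently with a word-punct rule — maximal runs of word characters or of
non-word, non-space characters — and context windows never cross the section
boundary; at document edges the context is truncated, never padded.

A FoT's descriptors are its multi-n-grams: all distinct uppercased
substrings of length 1..n_max of each member token, unioned across tokens
(grams never span token boundaries; set semantics, so a repeated substring
counts once).  n_max defaults to 5; longer grams become nearly unique in a
training set and stop generalising.

Fitting is pure counting — N, N_k, N_i, N_ik — from which the class priors
and per-gram conditionals follow as ratios.  Scoring uses the bounded
B-statistic

    S0_k = 2 N_k/N − 1,
    S_k  = sin(arcsin(S0_k) + A),
    A    = mean_i [arcsin(2 N_ik/N_i − 1) − arcsin(S0_k)],
    B_k  = (S_k − S0_k)/(1 − S_k S0_k).

Numerical conventions, all exercised by tests:

- **Centring.** Each arcsine term is taken relative to the prior's arcsine,
  so a gram whose conditional equals the prior contributes exactly zero, and
  an empty (or entirely unseen) descriptor set gives A = 0, S_k = S0_k and
  B_k = 0 — the "no information" value.
- **Mean vs sum.** A is the mean of the centred terms by default; a raw sum
  (the `sum_mode="sum"` flag) is retained for comparison but lets long
  fragments wrap the sine argument, which is why the mean is the default.
- **Extreme conditionals.** N_ik/N_i of exactly 0 or 1 is left intact; the
  arcsine bound (±π/2) is the mechanism that keeps such grams from
  dominating, so no epsilon flooring is applied.  Optional Laplace smoothing
  ((N_ik+α)/(N_i+2α), default α = 0) is available but off.
- **Unseen grams.** Grams with N_i = 0 (never seen in training) are skipped,
  equivalent to contributing the prior.
- **Degenerate cases.** |S0_k| = 1 (single-class model) and the 0/0 Möbius
  case both define B_k = 0.  B_k is clipped to [−1, 1] against rounding.

Leave-one-out scoring decrements the held-out FoT's own contributions
(N−1; N_k−1 for its label and, for base chemical types, also for the union
class CNE; N_i and N_ik down by one for each gram of its descriptor set) and
rescores; tests verify bit-level agreement with full retraining.  Exclusion
uses the same set semantics as fitting.

## Calibration

P_c and P_nc come from two independent one-vs-rest fits on the training
set's leave-one-out B values: P_c from the CNE-vs-rest curve on B_CNE, P_nc
from the NON_CNE-vs-rest curve on B_NON_CNE.  They are therefore not
complements: a token with conflicting evidence on the two axes can have both
probabilities small (rendered blue by the colouring).

Each curve is built from the two *class-conditional* distributions of B with
equal class weight: the B axis is binned (bin edges from per-class
quantiles, q = 20 by default, so the minority class keeps resolution), each
bin's value is (n₊/N₊)/((n₊/N₊)+(n₋/N₋)), the values are made nondecreasing
by weighted pool-adjacent-violators (the B-statistic orders evidence, so the
membership curve must not invert between noisy bins), and the result is
interpolated piecewise-linearly with constant extrapolation beyond the outer
bin centres, clipped to [0, 1].  A least-squares polynomial (degree 5)
through the binned frequencies is available as an alternative.

The equal-class-weight construction is deliberate.  The corpora this model
is trained on are heavily imbalanced (background:chemical ≈ 15:1), and the
prevalence-weighted posterior frequency caps P_c near 1/(1+R·ε) — in
practice about 0.5 — even on stretches of the B axis populated exclusively
by chemical fragments, which would make a threshold of 0.3 on P_c − P_nc
unreachable.  Building the curves from the per-class distributions makes
them prevalence-free: P_c → 1 where only the chemical distribution has
mass.  This also reproduces the intended anchor behaviour of the colouring
(P_c = 1/P_nc = 0 for clear chemical evidence at any imbalance).

## Evaluation

Invariant accuracy IA = #[E(FoT₊) > E(FoT₋)]/(#FoT₊·#FoT₋) is computed by a
sort-and-count equivalent of full pair enumeration.  Ties count zero under
the strict definition (the default); `ties="midrank"` scores them 0.5 for
exact comparability with ROC AUC.  Confusion metrics with a zero denominator
are reported as missing, never as 0.

Cross-validation splits by document (seeded shuffle into k near-equal
folds), so a target and its context can never straddle a fold boundary.
Per fold the model is refitted, calibrated on its own LOO B values, and
applied to the test documents; confusion counts are pooled (micro) across
folds, which is stable for the rare classes.  Entity-level scoring uses
exact span equality against the gold annotation; an overlap-based relaxed
comparison would only raise the reported numbers.

## Extraction and filters

Tokens with P_c − P_nc strictly above T (default 0.3) that survive the
token-level filters form maximal runs of consecutive tokens; each run
becomes one entity whose surface is the original text from first to last
member (inter-token punctuation preserved), scored by the mean member
score.  Entity-level filters then drop whole candidates.

Default token rules: bare numerics (`[+-]?\d+([.,]\d+)*`), punctuation-only
tokens (which covers lone brackets), and the *overrepresented non-entity
surface* rule — a stop list derived from training counts that excludes any
surface seen at least 10 times as a training target with at most 5% of
those occurrences labelled chemical.  The last rule addresses a structural
property of bag-of-grams scoring with a symmetric window: the descriptor
set of a word adjacent to a chemical mention differs from the mention's own
set only by one swapped background token, so frequent function words next
to entities inevitably score high; excluding surfaces that training shows
are (nearly) never entities removes them from candidacy without touching
novel words.  Default entity rules: replacement/non-printable characters
("incorrect encoding"), unbalanced brackets, single non-alphanumeric
characters.  All rules live in plain data and can be replaced by a config
file (`cner write-filters`, `--filters`).

## Synthetic corpus generator

The generator produces CHEMDNER-format corpora (tab-separated abstracts +
stand-off spans, offsets in code points per section) whose statistical
structure matches what the classifier exploits in real abstracts:

- background text from a fixed 160-word vocabulary, with commas and
  sentence stops, so punctuation also occurs in non-chemical contexts;
- per-class surface grammars: systematic morpheme chains
  ("chloromethhexanol"), element-digit formulas ("C6H12O6"), 2–4 letter
  uppercase abbreviations, family stems with collective suffixes
  ("flavonoids"), and a fixed trivial-name lexicon;
- class weights proportional to the class sizes of a large expert-annotated
  reference corpus (merged-chemical prior ≈ 1:16);
- mention idioms with fixed per-class probabilities: two-word names
  (systematic 62%, family 66%), salts ("chloroquine phosphate", trivial
  54%), comma-separated lists of 3–4 names, parenthesised abbreviations and
  formulas, a 5% share of punctuated locant names ("1,2-dimethylhexane"),
  and a 4% share of bare single-word mentions.

The idiom mix is not cosmetic.  Bag-of-grams scoring is position-blind, so
a single chemical word flanked by two ordinary words is statistically
indistinguishable from its own neighbours, and no threshold can extract it
exactly; real chemical text is extractable because mentions are mostly
multi-word, list-separated, or punctuation-flanked, and the generator
reproduces those conditions.  The residual bare mentions and locant names
(whose numeric/punctuation members the token filters remove) are
deliberate, known recall losses.  The entity rate (default 0.06) is the
expected fraction of tokens inside gold spans; the per-slot mention
probability is derived from it with a Monte-Carlo estimate of tokens per
mention event.  What the generator does **not** emulate: English syntax,
misspellings, document-level topic drift, hyphenated line breaks, and
entity surfaces shared between classes — so passing tests demonstrate the
pipeline's correctness and its behaviour under realistic imbalance and
idiom structure, not performance on real PubMed text.

## Problem sizes and defaults

The reference configuration is 200 documents (~15,700 tokens, ~900 chemical
tokens, ~700 gold mentions), window 1, n_max 5, T = 0.3, q = 20 calibration
bins — sizes at which a full 5-fold cross-validation with per-fold LOO
calibration and a whole-corpus LOO evaluation complete in well under a
minute on one core.  Window 1 and n_max 5 are the accuracy/complexity
optimum for this family of models; larger windows blur the target token's
signal and longer grams stop repeating.

## Known limitations

- Exact-span extraction of isolated single-word mentions is impossible in
  principle under a symmetric context window (see above); such mentions are
  recovered only when flanked by punctuation, lists, or stop-listed words.
- Names containing digits or punctuation lose those members to the default
  token filters and are extracted only partially; relaxing the filters
  trades this against spurious numeric extractions.
- The calibration is trained per corpus; a model applied to text from a
  very different domain should be recalibrated.
- Per-character scoring uses only the grams of the token that cover the
  position (no context), so letter colours within a token vary only where
  the covering gram sets differ.
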