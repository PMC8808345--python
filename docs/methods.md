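# Methods

This note documents the models and procedures implemented in `endsner`,
the choices made where the design was genuinely open, and what the
synthetic-corpus experiments do and do not demonstrate.

## Text normalization and coordinates

All annotation, tagging, and scoring happen on *normalized* text; raw post
text is related to it by a total, monotone offset map. Normalization
(1) removes maximal `#`-initiated word tokens outright — the whole token,
not just the `#`; (2) replaces each emoji codepoint or ZWJ-joined sequence
by its CLDR English short name, inserted as plain space-separated words
(multi-word names therefore become multiple tokens); and (3) collapses
whitespace runs to single spaces and strips the ends. The short-name table
is pinned and shipped with the package (`data/cldr_short_names.tsv`,
CLDR v44 annotations); codepoints missing from it fall back to their
Unicode character names, lower-cased. Normalization is idempotent, and the
offset map is defined for every raw offset, with characters inside removed
regions mapping to the position of the gap.

Annotations supplied on raw text are projected forward: a span lying
entirely inside a removed region (e.g. inside a removed hashtag) is
dropped with a warning and counted; a partially removed span is an
alignment error, because no faithful normalized image exists. Whether
annotation offsets should be interpreted before or after normalization is
not dictated by the data format itself; this package standardizes on
*after* (the JSONL corpus format carries normalized text), and `annotate`
covers the raw-offsets case via projection.

The tokenizer splits on whitespace and emits every punctuation or symbol
character (Unicode categories P and S) as its own one-character token.
One canonical tokenizer is used for the whole pipeline — training,
look-up, and scoring — so that token boundaries can never disagree
between stages.

## Tag encodings

IO is the default encoding: tokens inside a brand span are `I-BRAND`,
flavors `I-FLAVOR`, everything else `O`. IO cannot represent a boundary
between two adjacent same-type entities; decoding merges them into one
span. This information loss is inherent to the scheme, accepted for its
simplicity, and surfaces in one measurable way: a look-up prediction
adjacent to a same-type prediction merges when routed through tags, which
can shift an exact-match score by a span or two per thousand. IOB and
BILOU are supported behind the same encode/decode interface and do not
lose adjacency information. Decoding is lenient for continuation tags
without an opener (they start a new span); structurally invalid tag
*strings* are rejected.

## The CRF

A linear-chain CRF scores a tag sequence as the sum of per-position
state scores `w·f(x, t, y_t)` and transition scores `A[y_{t−1}, y_t]`.
The feature templates are fixed: current-token identity (lower-cased),
lower/upper/title-case and digit indicators, prefix and suffix (default
length 3), the case-shape indicators of the previous and next tokens, and
BOS/EOS pseudo-features at the edges (pseudo-features, not extra tags).
The feature space is built from the training split only; unseen features
at prediction time contribute zero. Tag order is fixed (`O` first), which
makes Viterbi tie-breaking deterministic: equal-scoring paths resolve to
the earliest tag in the tag set, earliest position first.

Training minimizes the elastic-net-penalized negative log-likelihood

    Σ_i (log Z(x_i) − score(y_i | x_i)) + l1·‖θ‖₁ + l2·‖θ‖₂²

with defaults `l1 = 0.1`, `l2 = 0.1`, `max_iterations = 100`,
`gradient_tolerance = 1e-5`. These defaults are design choices of this
package, not reconstructions of any particular study's settings. The
gradient of the smooth part is expected-minus-empirical feature counts
plus `2·l2·θ`, computed by forward–backward; the implementation batches
all sequences into padded arrays and a sparse position×feature matrix, so
one objective evaluation is a handful of vectorized passes. The
non-smooth L1 term is handled exactly by the split-variable
reformulation θ = u − v with u, v ≥ 0 and penalty `l1·Σ(u+v)`, solved
with SciPy's bound-constrained L-BFGS-B; at the optimum this is
equivalent to orthant-wise methods, and it reuses a vetted optimizer
rather than a hand-rolled one. With `l1 = 0` plain L-BFGS-B on θ is used.
Training is deterministic given corpus and configuration; hitting the
iteration cap logs a warning and returns the current iterate (with the
default cap of 100 the held-out scores are already stable; the cap
trades tail-end convergence for predictable runtime).

All inference is in log space with log-sum-exp stabilization. The
forward recursion, posterior marginals, and Viterbi are verified against
exhaustive enumeration on small instances (T ≤ 4, L ≤ 3) to 1e-8, the
analytic gradient against central finite differences to relative error
1e-4, and log Z against the independent backward recursion.

A minimal `Tagger` protocol (`fit(corpus)`, `predict(tokens)`) decouples
the evaluation harness from the CRF so that other taggers — including
neural ones — can be cross-validated with the same machinery; the
dictionary baseline already uses it.

## Dictionary look-up baseline

Lexicon entries are normalized with the same pipeline as posts
(lower-cased, tokenized); matching is case-insensitive and anchored to
token boundaries, so `pop` never matches inside `lollipop`. Overlapping
candidate matches resolve longest-first, then leftmost — the standard
gazetteer convention. A raw-substring mode (`mode="substring"`) is
available for the maximal-recall reading of dictionary look-up; the
token-bounded mode is the default because unanchored matching degenerates
on short generic names. Output spans never overlap.

## Evaluation

Scoring is at the entity (span) level, micro-averaged within entity type;
brand and flavor are always reported separately, and no macro average is
computed. Exact matching requires identical (start, end, label). Partial
matching credits a same-label prediction overlapping a gold span by at
least one character, with one-to-one greedy pairing by descending
overlap (ties: earlier gold, then earlier prediction); partial true
positives are never fewer than exact ones. Zero-denominator metrics are
*undefined*, reported as `None`/`N/A`, and excluded from fold means with
a logged note — treating 0/0 as 0 would silently punish a tagger for
predicting nothing on a fold with nothing to find.

Cross-validation partitions posts (not tokens) into k seeded, near-equal
folds via scikit-learn's shuffled `KFold`; each fold is scored with a
tagger fitted on the remainder, and the report carries per-fold results
plus mean and sample SD (n−1 denominator). Cohen's κ is computed from
the confusion matrix of two equal-length token-level tag sequences, with
the degenerate p_o = p_e = 1 case defined as 1; token level is a choice
(mention- or post-level units would also be defensible), made because it
is reproducible from tag sequences alone. Mention-share tables group
mentions by case-folded surface form, with shares rounded half-up to one
decimal and rows sorted by count descending then name ascending.

## Synthetic corpus

The generator emulates the summary shape of a manually annotated
vaping-post corpus: ≈35 tokens per post, ≈0.54 brand and ≈0.22 flavor
mentions per post (per-post counts are ⌊rate⌋ plus a Bernoulli fractional
part, so a rate of 1 forces exactly one mention), hashtag and emoji
noise, and entity surfaces drawn from configurable vocabularies with
casing variants (canonical 55%, lower 15%, upper 10%) and, for
multi-word brands, squashed spellings ("Puff Bar" → "PuffBar", 20%).
Posts are assembled from short entity-slot phrase templates plus generic
filler; raw text (with hashtags and real emoji) is then pushed through
the actual normalization pipeline, so gold spans on normalized text are
exact by construction and every generated post exercises the
preprocessing code. Adjacent same-type entities are explicitly separated
by a filler word so that the IO round trip is lossless on generated data.

Companion lexicons mirror the complete-versus-partial list contrast:
FULL holds every canonical brand name; TRUNCATED the top half by planted
frequency (a top-sellers list); POLLUTED adds generic homograph words
("pop", "epic", "carbon", …) that the generator also plants as plain
non-entity text — added entries can only add false positives, so
POLLUTED's span-level recall equals FULL's while its precision drops.

What the generated data does *not* emulate: real token frequency
distributions, spelling errors beyond the scripted variants, multilingual
posts, brand names colliding with filler vocabulary, or discourse
structure. Consequently the CRF's near-ceiling scores on synthetic
corpora (closed vocabularies with consistent context are close to
separable) say that the estimator and harness are correct, not that
comparable scores would be reached on real posts; the qualitative
orderings — learned tagger above dictionary look-up on recall, larger
list above smaller list — are the transferable result.

## Problem sizes and numerics

The benchmark configuration used by the acceptance script and tests is
1000 posts, 50 brands, 30 flavors, homograph rate 0.1, 5 folds; it was
chosen as the smallest corpus on which fold-level scores are stable to a
few hundredths. Inference tolerances: enumeration agreement 1e-8,
marginal row sums 1e-12, gradient check 1e-4 relative at step 1e-5.
Degenerate inputs: empty text normalizes to empty; empty token sequences
decode to empty tag sequences and predict no spans; zero-length inference
(T = 0) raises; an empty training corpus is a configuration error.

## Known limitations

- IO adjacency merging (above) slightly perturbs exact-match scores of
  any tagger routed through tag sequences.
- The emoji short-name table is a pinned subset; uncovered codepoints get
  Unicode names, which differ from CLDR wording for some characters.
- The L1 path doubles the parameter vector; for very large feature
  spaces an orthant-wise optimizer would halve memory.
- `cohen_kappa` is token-level and two-rater only.
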