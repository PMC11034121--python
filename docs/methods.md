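# Methods

This note documents the models and procedures implemented in `recsoi`, the
assumptions behind them, the numerical choices, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Problem setting

A corpus supplies (a) papers segmented into sentences, where some
sentences are labeled as statements of ignorance (SOIs) with one of
thirteen ignorance categories, and (b) for each paper's first author, the
sentence-segmented abstracts of their strictly earlier first-author
papers.  Only five categories signal a pursuable research direction —
full unknown, explicit question, problem or complication, future work,
future prediction — and only SOIs in this subset are recommendation
candidates.  The temporal split (profiles from text strictly preceding
the candidate pool) is a hard invariant, machine-checked by
`temporal_split_check`; `time_rank` is an integer ordinal rather than a
date because only the strict "prior to" relation is ever used.

Category labels are canonicalized (Unicode NFC, lowercase, collapsed
whitespace, slash read as "or"), so printed variants such as
"Problem/complication" and "problem or complication" coincide.  Sentence
segmentation is assumed upstream; the package deliberately bundles no
tokenizer for document segmentation.  One category per sentence is
representable; multi-label annotation is out of scope of the format.

## Researcher profiles

A profile is a *list* of vectors, one per prior abstract (capped at 5,
sampled uniformly when an author has more; the cap models junior
researchers, and uncapped operation is available via the `cap`
parameter).  Each abstract vector is a weighted mean of its sentence
embeddings:

    weight(p) = −(2·(0.5 − p))  if p < 0.5,  2·(p − 0.5)  otherwise
    embedding(a) = Σᵢ weight(sᵢ)·eᵢ / Σᵢ |weight(sᵢ)|

where p is the probability, under a per-author logistic-regression
discriminator on TF-IDF features, that the author wrote sentence sᵢ.
Both branches of the weight reduce algebraically to 2p − 1 (a tested
identity); the piecewise form is kept because it states the intent —
sentences *more likely than not* the author's pull the abstract vector
toward themselves, the rest push it away.

**Class balancing is load-bearing.**  The discriminator is trained on
abstract-level TF-IDF vectors, one positive author versus all others.  At
realistic corpus sizes the positive class is a few abstracts in hundreds
or thousands, and a plain fit then puts *every* sentence probability far
below 0.5: all weights turn negative and, because the denominator uses
|weight|, the abstract embedding degenerates to (approximately) the
*negated* sentence mean — the profile points away from the author's own
topic and the ranking inverts.  We therefore fit
`LogisticRegression(C=1, penalty=l2, class_weight="balanced")`: balancing
recenters the probability scale so that 0.5 means "more the author's than
not" against an even prior, which is the only reading under which the
weight formula does what it is designed to do.  The C = 1 ridge setting
matches the TF-IDF+LR ranking baseline; the discriminator is deliberately
shared between the two roles.  Training at abstract granularity and
applying at sentence granularity (both in the single corpus-fitted TF-IDF
space) is retained as specified.

If all weights underflow (an uninformative discriminator, p ≡ 0.5), the
abstract embedding falls back to the unweighted mean with a warning
rather than erroring: the degenerate case is reachable and a mean is the
correct limit.

## Embeddings

The embedding contract only requires that texts sharing more vocabulary
land closer in the space.  The default `offline-hash` backend provides
that property deterministically with no model download: lowercase
whitespace tokens are hashed (BLAKE2, stable across processes) into 4096
signed buckets, the bag vector is projected through a seed-fixed Gaussian
matrix, and the result is L2-normalized; empty text maps to the zero
vector.  Default dimension is 384, mirroring the dimensionality of the
MiniLM sentence encoder that the `pretrained` adapter loads; any dim ≥ 2
is accepted.  Sentence embeddings are *not* re-normalized before
averaging or distance computation — the aggregation equation is applied
to the vectors as produced — and this choice is a documented sensitivity
knob.

TF-IDF dialect (shared by the discriminator and the TF-IDF+LR baseline):
lowercase unigrams, scikit-learn tokenization (`\b\w\w+\b`), no stop
list, smoothed idf = ln((1+N)/(1+df)) + 1, L2-normalized rows.  The
vocabulary is fitted once on the full abstract collection so all authors
share one feature space; the fitted model serializes to JSON with its
dialect flags embedded.

## Ranking

`recsoi` scores a candidate by the minimum Euclidean distance to any
profile vector and ranks ascending.  The sentence-embedding baseline
collapses the author to a single mean-of-means vector; the TF-IDF+LR
baseline ranks by descending discriminator probability on each SOI's
TF-IDF vector; the random baseline draws uniformly without replacement.
All four return exactly min(k, n) distinct items and break score ties by
lexicographic SOI id — the determinism claim ("same profile, same pool,
same recommendations") requires a data-independent tie rule, and no such
rule is stated elsewhere.  Distances are never compared across authors.
A cosine variant is intentionally not part of the evaluated surface.

## Evaluation

Three relevance heuristics approximate "relevant to researcher r":

* **first_author** — the SOI's paper is first-authored by r;
* **co_authors** — the SOI's paper's first author appears as co-author on
  some paper where r is first author (r is never their own co-author; the
  order-weighted refinement of this heuristic is explicitly excluded);
* **concepts** — the SOI shares ≥ 1 concept string (exact match after
  lowercase/NFC) with the union of concepts in r's abstracts.  Authors
  sharing no concept with any candidate are excluded from this
  heuristic's denominator only.

`MAP_∃@k` is the fraction of evaluated authors with at least one relevant
item in their top k; `MAP@k` the mean relevant fraction.  Provable and
tested properties: 0 ≤ MAP@k ≤ MAP_∃@k ≤ 1, and MAP_∃ is non-decreasing
in k.  The author count (denominator of the MAP formulas) and the SOI
pool size (denominator of the hypergeometric expectation) are kept as
separate quantities (`authors_evaluated` vs `n_sois`).

Confidence halfwidths: each percentage is a mean of Bernoulli trials, so
a binomial interval applies.  `wald_halfwidth` implements the
normal-approximation width z·√(p(1−p)/n).  `wilson_halfwidth` implements
the Wilson score width, which unlike Wald is strictly positive at p = 0
and — empirically, across every interval cell of the reference evaluation
we checked, including the 0% random rows and the extreme-proportion
small-n cells — reproduces the published ± values to the printed decimal.
(Two cells differ by exactly one final-digit rounding step, consistent
with the values having been rounded twice.)  The report object uses the
Wald width by default; Wilson is available for exact agreement at extreme
proportions.

The analytic random row uses the hypergeometric expectation k·n_R/n of
relevant items among k uniform draws without replacement, and reports the
percentage of authors for which that expectation reaches 1.

## Context highlighting

The paragraph containing a SOI is extracted as the ordered sentences
sharing its paragraph index; canonical paragraph text joins sentences
with single spaces after NFC normalization, and all substring checks run
on this form.  Strategies: no highlight; the single previous sentence
(empty when the SOI opens its paragraph); and LLM-selected passages.

LLM outputs pass through strict validation: the response is split on
newlines, surrounding straight/curly quotes are stripped, and a candidate
is kept only if it is a verbatim substring of the paragraph and not
exactly the SOI text.  Rejected candidates are annotated `is-soi`,
`modified-text` (shares vocabulary with the paragraph but is not
verbatim) or `extraneous` (no token overlap).  Passages *containing* the
SOI plus extra context are kept — the exclusion is exact-match only.
Validation is idempotent.  The prompt template is stored as a versioned
text asset with two SOI placeholders; substitution is plain string
replacement.  The bundled adapter is a synthetic offline mock (highest
token overlap with the SOI, excluding the SOI) so the whole pipeline is
testable and deterministic; network backends plug in behind the same
single-method contract.  How a live model delimits multiple passages in
one response is not standardized; the newline/quote splitting rule here
is this package's own convention.

## Study design and analysis

Each of n SOIs is judged under all three presentation strategies, so a
session has 3n trials (90 for the standard 30 SOIs).  Randomization is by
block: per SOI, the three strategies are randomly assigned to the three
blocks; each block is then shuffled; and whole orders are
rejection-sampled (cap 10,000 attempts) until every pair of same-SOI
trials is at least `min_separation` = 5 positions apart, with the gap
measured as a difference of positions.  Coverage, plan size and
separation are machine-checked invariants.

Analyses per participant: the 8-way combination breakdown (which strategy
subsets were useful per SOI) as percentages rounded half-up to one
decimal; the any-useful rate (identically 100 − the "nothing" share);
pairwise preference counts (A∧¬B / B∧¬A / both / neither, a partition of
the SOIs); and paired t-tests on per-SOI 0/1 usefulness differences,
two-sided by default with a one-sided flag, optionally conditioned on the
paragraph-only judgment.  Significance is flagged at both 0.05 and 0.1.
Degenerate inputs are defined, not exceptional: all-zero differences
yield a no-test result; constant non-zero differences yield the t → ±∞,
p → 0 limit.  Aggregation is per item (per SOI) within a participant; a
per-participant aggregate variant is not implemented.

## Synthetic-data generator

The generator produces corpora with the three statistical features the
recommender relies on, each a knob:

* **Topics.**  `n_topics` disjoint vocabularies of 200 terms with
  Zipf-shaped (exponent 1.1) frequencies; the top 30 terms of each topic
  form its concept pool, so concept tags fall out of token sampling.
  `topic_overlap` replaces any content token with one of 500 shared
  background terms; at 1.0 all authors write indistinguishable text and
  ranking collapses to chance (a tested monotone trend).
* **Author signatures.**  Each author carries 15 personal terms; sampled
  sentences take 6 topic tokens and 4 signature tokens.  This models the
  project-specific vocabulary that dominates a junior researcher's few
  abstracts and is exactly the author-level signal the first-author
  heuristic rewards (and that the heuristic's known weakness — dependence
  on the author's particular words — presupposes).
* **Generic SOIs.**  With probability `generic_soi_fraction` a paper's
  SOI is drawn from a fixed set of concept-free ignorance phrasings
  ("further studies are needed…"); otherwise a topical token bag is
  wrapped in an ignorance template and concept-tagged.  This reifies the
  generic-statement failure mode as a controllable parameter: at fraction
  1, no SOI carries any concept and the concepts ground truth is empty.

Profile lengths follow the empirical 1–5 abstracts-per-author
distribution (weights 72/57/38/42/291).  Each author first-authors
exactly one paper with 3–6 recommendable SOIs plus one
non-recommendable SOI (category "question answered by this work") to
exercise filtering; 1–3 co-authors are sampled within the author's
topic; abstracts receive time ranks strictly below all papers, so the
temporal split holds by construction.  Ground-truth relevance sets are
built by direct joins at generation time, independently of the
evaluation module's predicates, and a cross-module test asserts exact
agreement on every (author, SOI) pair.

What the generator does **not** emulate: natural language (token bags
only — so results transfer to the lexical-overlap component of real
sentence encoders, not their semantics), noisy or multi-label concept
annotation, authors with zero abstracts, cross-topic collaboration, or
full-scale pools (tens of thousands of SOIs).  Passing recovery tests
therefore demonstrate that the pipeline recovers planted author- and
topic-level structure at desk scale, not field performance on real
literature.

The recovery experiment runs simulate → profile → rank → score per
replicate, with replicate r seeded at seed + r.  The standard conditions
(50 authors, 5 topics, disjoint vocabularies, no generic SOIs, 10
replicates) take ~15 s on one CPU; at those conditions the profile-based
recommender reaches MAP_∃@5 ≈ 0.8 under the first-author ground truth
against ≈ 0.1 for the random baseline, and raising the generic fraction
to 0.9 roughly halves it — the directional signature of the generic-SOI
failure mode.  (These numbers are recomputed, not asserted, by
`scripts/acceptance.py`; the test suite asserts the ≥ 0.5 margin and the
degradation direction.)

## Numerical and interface choices

* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; no global state.
* JSONL canonical form: record order authors → papers → abstracts → SOIs,
  sorted keys, compact separators; load→write is a byte-level fixed
  point, which the round-trip tests exploit.
* Weight-sum underflow threshold 1e-12; distance computation uses the
  vectorized ‖a‖² − 2a·b + ‖b‖² expansion clipped at 0 before the square
  root, verified against per-pair norms to 1e-9.
* Percentages are formatted to one decimal, rounding half-up
  (`decimal.Decimal`), matching the reporting convention of the study
  tables.
* The command-line interface (`recsoi validate|simulate|profile|rank|
  evaluate|context|study`) is a thin click layer over the library; every
  capability is available as a plain function.

## Limitations

* The offline embedder captures lexical overlap only; conclusions about
  semantic matching require the `pretrained` adapter and real text.
* The discriminator's negative class is "all other authors' abstracts",
  with no subsampling; extremely large corpora would make per-author
  training quadratic in practice (mitigated here by sharing the TF-IDF
  matrix across authors).
* Cold-start authors (no prior abstracts) raise an error by design;
  proxy-author substitution is the caller's decision.
* Name disambiguation, SOI classification, concept extraction and live
  LLM calls are all upstream of this package's contract: labels,
  concepts and LLM outputs are consumed as inputs.
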