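# Methods

## Problem and statistic

The pipeline measures lexical concordance between K stochastic replicate
answers to a question and that question's single curated reference text.
Concordance is TF-IDF cosine similarity computed over bag-of-words
representations; the per-question statistic is the arithmetic mean of the K
replicate-vs-reference cosines. The method captures keyword overlap only —
no word order, syntax, or semantics beyond shared lemmas.

## Normalization

Steps run in a fixed order: tokenize (lowercase, split on any
non-alphanumeric character; hyphenated words split) → drop digit-bearing
tokens → lemmatize → remove stop words. Stop-word removal runs after
lemmatization so inflected fillers ("was" → "be") are caught by a
lemma-form list. Two decisions here are genuinely open and were fixed once:

* **Whole-token numeral dropping.** Tokens containing *any* digit ("5mg",
  "b12") are removed entirely, not just pure numerals. This changes the
  vocabulary (e.g. vitamin "b12" disappears); the alternative — keeping the
  alphabetic remainder — would manufacture tokens that never occurred.
* **Lemmatizer.** A pinned rule-based English backend: a table of common
  irregular forms plus suffix rules (-ies/-es/-s, -ing/-ed with
  final-consonant undoubling), with identity as the fallback for unknown
  forms so the map is total and deterministic. It under-lemmatizes rare
  irregulars; because both sides of every comparison pass through the same
  map, this biases similarity scores much less than it would bias any
  single document's token list. The stop-word list is a versioned file in
  `src/concordex/data/`; nothing is fetched at run time.

## TF-IDF variant

Pinned to: raw term counts; smoothed idf `ln((1+N)/(1+df)) + 1`; Euclidean
normalization — the same variant scikit-learn uses by default, which the
test suite exploits as an independent cross-check. The smoothed form keeps
idf positive even for terms present in every document; with unsmoothed idf
a 2-document corpus would zero out all shared content and make every
similarity 0. One global vocabulary per run is built over **all** analysed
documents (selected replicates plus references), so idf reflects
corpus-level rarity; document frequencies are *not* updated when null
random texts are scored.

The element-wise mean of replicate vectors (`w_j = (1/N) Σ_i e_ij`) is
implemented as a per-term mean over replicates and exposed as the
`aggregate_vector` summary mode; the default `mean_of_scores` mode averages
the per-replicate cosines instead, matching the per-question averaging the
study design describes.

## Null model and significance

The null hypothesis is "the response is random text with the reference
corpus's word statistics". Random texts draw tokens i.i.d. from the
unigram distribution pooled over all reference documents (pooling
stabilizes estimates for short references; per-question length matching
preserves the length dependence of cosine similarity).

The null distribution is built on **the same statistic that is observed**:
each of the B = 1000 null samples is the mean of K random-text cosines,
with the K text lengths matched to the observed replicates' token counts.
This makes observed and null values exchangeable under the null hypothesis,
so the decision rule — flag a question when its observed mean strictly
exceeds the empirical 95th percentile (linear interpolation between order
statistics) — rejects at its nominal 5% level. A null built from single
reference-length texts is available by omitting the replicate lengths, but
it is not calibrated for a mean-of-K statistic and is not the pipeline
default. The add-one empirical p-value `(1 + #{null ≥ obs})/(B + 1)` is
reported for audit; the percentile rule decides significance. No
multiple-testing correction is applied.

Since TF-IDF weights depend only on term counts, null texts are sampled
directly as multinomial count vectors over the unigram support —
distributionally identical to drawing token sequences and counting them,
and roughly two orders of magnitude faster at B = 1000 per question. A unit
test pins the equivalence of the count path and the sequence path.

## Synthetic corpora

The generator emulates only the bag-of-words statistics the method
consumes. Per question, a reference of `reference_length` tokens (default
120) is drawn from a question-specific Zipf-weighted distribution
(exponent 1.0 by default — natural term frequencies are heavy-tailed) over
a shared vocabulary; each of K (default 10) responses of `response_length`
tokens (default 80) draws each token from the reference's empirical
distribution with probability ρ and from a disjoint distractor vocabulary
otherwise, so ρ is the expected on-topic token fraction and subject mean
similarity is monotone in it. Default subjects are the five preclinical
areas (biochemistry … pharmacology) with ρ = 0.1 … 0.5. Vocabulary sizes
default to 250 shared + 250 distractor pseudo-words — comparable to the
distinct-lemma count of a few hundred short clinical passages. Pseudo-words
are consonant-only lowercase strings, so they contain no digits, match no
stop word, and are fixed points of the lemmatizer: generated texts survive
normalization verbatim.

A separate null-corpus generator draws every response i.i.d. from the
pooled reference unigram distribution, making the significance rule's null
hypothesis hold exactly; running the full pipeline over 500 such questions
measures the empirical type-I error (the acceptance script does this at
B = 1000, a few minutes on one CPU).

What passing these tests does *not* show: robustness to real prose
(grammar, synonymy, paraphrase), to references of very unequal length, or
to model answers that are topically related without sharing lemmas — the
statistic is blind to meaning that does not surface as shared vocabulary.

## Numerical and design choices

* Cosine accumulation iterates shared terms in sorted order, so
  `cos(a, b) == cos(b, a)` exactly; values are clipped to [0, 1] against
  last-ulp rounding.
* Empty documents vectorize to all-zero vectors (`normalized=False`) and
  score 0 against everything.
* Public float contracts use 1e-9 tolerance; brute-force oracle tests use
  1e-12.
* Per-question RNG streams are spawned from the master seed
  (`SeedSequence.spawn`), so results are bit-reproducible and independent
  of question order; fixed seed ⇒ byte-identical output files.
* PCA projection: column-centered document×term matrix, SVD, top-2
  components, each component's sign fixed so its largest-magnitude loading
  is positive (deterministic output).
* Sensitivity table SD is computed across questions (of the per-question
  median replicate score), not across replicates; noted in the output
  schema.
* The corpus format accepts any K ≥ 1 per question; `replicate_mode`
  ("all" vs "first_n", default all) surfaces collected-vs-compared
  replicate subsets as configuration rather than hiding them.
* Percentages in the counts table are recomputed from the counts and
  printed to one decimal.

## Limitations

Keyword-level similarity only; English-only normalization; a light
rule-based lemmatizer rather than a full morphological analyzer; no
parametric or higher-order (n-gram) null; subject comparisons are
descriptive (means/SDs), with no between-subject inference.
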