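"""Randomized-text null distributions and per-question significance calls.

The question of interest is whether a model answer resembles its curated
reference more than chance would produce.  "Chance" is operationalized by
random texts that match the reference corpus's unigram word distribution:
tokens are drawn i.i.d. from the pooled relative frequencies of all
reference documents.  The null distribution for a question collects B
similarity values of such random texts scored against that question's
reference, and a question is flagged significant when its observed summary
similarity strictly exceeds the null's 95th percentile.  An add-one
empirical p-value, ``(1 + #{null >= observed}) / (B + 1)``, is reported
alongside.

When the observed statistic is the mean of K replicate similarities, each
null sample is built the same way — the mean of K random-text similarities,
with text lengths matched to the observed replicates — so that observed and
null values are exchangeable under the null hypothesis and the rule rejects
at its nominal 5% level.  With no replicate lengths supplied, a null sample
is a single random text matched to the reference's own length.

Because the TF-IDF weight of a document depends only on its term counts,
null texts are simulated directly as multinomial count vectors; this is
distributionally identical to drawing token sequences and counting them,
and removes the dominant cost of the B=1000-per-question resampling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .normalize import TokenSequence
from .tfidf import SimilarityScore, Vocabulary, tfidf_vectorize

__all__ = [
    "UnigramDistribution",
    "NullDistribution",
    "SignificanceResult",
    "estimate_unigram",
    "random_text",
    "build_null",
    "test_significance",
    "DEFAULT_NULL_SAMPLES",
]

DEFAULT_NULL_SAMPLES = 1000
CRITICAL_QUANTILE = 0.95


@dataclass(frozen=True)
class UnigramDistribution:
    """Token relative frequencies estimated from a document pool."""

    terms: tuple[str, ...]
    probs: np.ndarray
    source: str = ""

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.terms, self.probs.tolist()))


@dataclass(frozen=True)
class NullDistribution:
    """B null similarity scores for one question's reference."""

    scores: np.ndarray
    reference_id: str = ""
    seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class SignificanceResult:
    observed: float
    p_value: float
    threshold_95: float
    significant: bool


def estimate_unigram(reference_docs: list[TokenSequence], source: str = "pooled-references") -> UnigramDistribution:
    """Pooled unigram distribution over all reference documents.

    ``P(term)`` is the pooled count of the term across the documents divided
    by the total pooled token count.
    """
    counts: dict[str, int] = {}
    total = 0
    for doc in reference_docs:
        for tok in doc.tokens:
            counts[tok] = counts.get(tok, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("cannot estimate a unigram distribution from all-empty references")
    terms = tuple(sorted(counts))
    probs = np.array([counts[t] for t in terms], dtype=float) / total
    return UnigramDistribution(terms=terms, probs=probs, source=source)


def random_text(length: int, dist: UnigramDistribution, rng: np.random.Generator) -> TokenSequence:
    """Draw ``length`` tokens i.i.d. with replacement from ``dist``."""
    if length < 1:
        raise ValueError("random_text length must be >= 1")
    idx = rng.choice(len(dist.terms), size=length, p=dist.probs)
    return TokenSequence(tokens=tuple(dist.terms[i] for i in idx), source_id="random")


def _null_scores_for_length(
    length: int,
    n: int,
    probs: np.ndarray,
    idf_support: np.ndarray,
    ref_support: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """n similarity scores of random texts of one length vs the reference.

    Samples term counts multinomially over the distribution's support and
    applies the pinned TF-IDF weighting restricted to in-vocabulary terms.
    """
    counts = rng.multinomial(length, probs, size=n).astype(float)
    weights = counts * idf_support  # idf is zero-padded for out-of-vocab terms
    norms = np.linalg.norm(weights, axis=1)
    dots = weights @ ref_support
    scores = np.zeros(n)
    nz = norms > 0
    scores[nz] = dots[nz] / norms[nz]
    return np.clip(scores, 0.0, 1.0)


def build_null(
    reference: TokenSequence,
    vocab: Vocabulary,
    dist: UnigramDistribution,
    B: int = DEFAULT_NULL_SAMPLES,
    rng: np.random.Generator | None = None,
    lengths: list[int] | None = None,
) -> NullDistribution:
    """Null distribution of the summary similarity for one question.

    Parameters
    ----------
    reference:
        The question's normalized reference document.
    vocab:
        The run's global vocabulary (null texts are scored against it
        without updating document frequencies).
    dist:
        Unigram distribution the random texts are drawn from (pooled over
        all references).
    B:
        Number of null samples (default 1000).
    lengths:
        Token counts of the observed replicate responses.  Each null sample
        is the mean of ``len(lengths)`` random-text similarities with these
        lengths, mirroring the observed mean-of-replicates statistic.  When
        omitted, one random text matched to the reference's own length is
        used per sample.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(reference) == 0:
        raise ValueError("reference document is empty")
    rng = rng if rng is not None else np.random.default_rng()
    if lengths is None:
        lengths = [len(reference)]
    if any(l < 1 for l in lengths):
        raise ValueError("all null text lengths must be >= 1")

    ref_vec = tfidf_vectorize(reference, vocab)
    idf_full = vocab.idf()
    # restrict the workspace to the sampling distribution's support;
    # terms outside the vocabulary get zero idf (ignored, as in vectorize)
    in_vocab = np.array([t in vocab.index for t in dist.terms])
    cols = np.array([vocab.index[t] if ok else 0 for t, ok in zip(dist.terms, in_vocab)])
    idf_support = np.where(in_vocab, idf_full[cols], 0.0)
    ref_dense = ref_vec.dense()
    ref_support = np.where(in_vocab, ref_dense[cols], 0.0)

    score_sums = np.zeros(B)
    for length, mult in sorted(Counter(lengths).items()):
        flat = _null_scores_for_length(length, B * mult, dist.probs, idf_support, ref_support, rng)
        score_sums += flat.reshape(mult, B).sum(axis=0)
    scores = score_sums / len(lengths)
    return NullDistribution(scores=scores, reference_id=reference.source_id)


def test_significance(observed: float | SimilarityScore, null: NullDistribution) -> SignificanceResult:
    """Significance call for one question against its null distribution.

    The question is significant when the observed summary similarity
    strictly exceeds the empirical 95th percentile of the null scores
    (linear interpolation between order statistics).  The reported p-value
    is the add-one estimator ``(1 + #{null >= observed}) / (B + 1)``, which
    can never be exactly zero.
    """
    obs = observed.value if isinstance(observed, SimilarityScore) else float(observed)
    scores = np.asarray(null.scores, dtype=float)
    if scores.size == 0:
        raise ValueError("null distribution is empty")
    threshold = float(np.quantile(scores, CRITICAL_QUANTILE, method="linear"))
    p = float((1 + np.sum(scores >= obs)) / (scores.size + 1))
    return SignificanceResult(
        observed=obs,
        p_value=p,
        threshold_95=threshold,
        significant=bool(obs > threshold),
    )
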