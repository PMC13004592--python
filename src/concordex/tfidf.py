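"""TF-IDF vectorization, replicate aggregation, and cosine similarity.

The similarity statistic is the cosine of the angle between TF-IDF vectors
built over a single shared vocabulary.  The variant is pinned:

* term frequency = raw count of the term in the document;
* inverse document frequency = ``ln((1 + N) / (1 + df)) + 1`` where ``N`` is
  the number of documents in the vocabulary-building corpus and ``df`` the
  number of those documents containing the term (the smoothed form keeps
  idf positive even for terms present in every document);
* each vector is Euclidean (L2) normalized.

With nonnegative weights the cosine lies in [0, 1]: 1 for identical
processed documents, 0 for documents sharing no terms.  One global
vocabulary is built per analysis run, over all model replicates and all
references, so idf reflects corpus-level rarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .normalize import TokenSequence

__all__ = [
    "Vocabulary",
    "TfidfVector",
    "AggregateVector",
    "SimilarityScore",
    "build_vocabulary",
    "tfidf_vectorize",
    "cosine_similarity",
    "aggregate_replicates",
    "question_similarity",
]

NORM_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class Vocabulary:
    """Shared term space: sorted term->index map plus document frequencies."""

    index: dict[str, int]
    n_docs: int
    df: np.ndarray  # document frequency per column index

    def __len__(self) -> int:
        return len(self.index)

    @property
    def terms(self) -> list[str]:
        return sorted(self.index, key=self.index.get)

    def idf(self) -> np.ndarray:
        """Smoothed inverse document frequency per column."""
        return np.log((1.0 + self.n_docs) / (1.0 + self.df)) + 1.0


@dataclass(frozen=True)
class TfidfVector:
    """Sparse L2-normalized TF-IDF weights for one document."""

    doc_id: str
    weights: dict[str, float]
    normalized: bool
    vocab: Vocabulary = field(compare=False)

    def dense(self) -> np.ndarray:
        out = np.zeros(len(self.vocab))
        for term, w in self.weights.items():
            out[self.vocab.index[term]] = w
        return out

    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


@dataclass(frozen=True)
class AggregateVector:
    """Element-wise mean of N replicate TF-IDF vectors for one question."""

    question_id: str
    weights: dict[str, float]
    n_replicates: int
    vocab: Vocabulary = field(compare=False)


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    doc_a: str = ""
    doc_b: str = ""


def build_vocabulary(docs: list[TokenSequence]) -> Vocabulary:
    """Build the shared vocabulary over all documents of a run.

    Terms receive lexicographically sorted indices; ``df(term)`` counts the
    documents containing the term at least once.
    """
    if not docs:
        raise ValueError("cannot build a vocabulary from an empty document list")
    df_map: dict[str, int] = {}
    for doc in docs:
        for term in set(doc.tokens):
            df_map[term] = df_map.get(term, 0) + 1
    terms = sorted(df_map)
    index = {t: i for i, t in enumerate(terms)}
    df = np.array([df_map[t] for t in terms], dtype=np.int64)
    return Vocabulary(index=index, n_docs=len(docs), df=df)


def _term_counts(doc: TokenSequence, vocab: Vocabulary) -> dict[str, int]:
    counts: dict[str, int] = {}
    for term in doc.tokens:
        if term in vocab.index:
            counts[term] = counts.get(term, 0) + 1
    return counts


def tfidf_vectorize(doc: TokenSequence, vocab: Vocabulary) -> TfidfVector:
    """TF-IDF vector of one document over the shared vocabulary.

    Terms absent from the vocabulary are ignored.  An empty document yields
    an all-zero vector flagged ``normalized=False``; every other vector has
    unit Euclidean norm.
    """
    counts = _term_counts(doc, vocab)
    if not counts:
        return TfidfVector(doc_id=doc.source_id, weights={}, normalized=False, vocab=vocab)
    idf = vocab.idf()
    weights = {t: c * idf[vocab.index[t]] for t, c in counts.items()}
    norm = math.sqrt(sum(w * w for w in weights.values()))
    weights = {t: w / norm for t, w in weights.items()}
    return TfidfVector(doc_id=doc.source_id, weights=weights, normalized=True, vocab=vocab)


def _check_same_vocab(a, b) -> None:
    va, vb = a.vocab, b.vocab
    if va is vb:
        return
    if va.index != vb.index or va.n_docs != vb.n_docs or not np.array_equal(va.df, vb.df):
        raise ValueError("vectors were built over different vocabularies")


def cosine_similarity(a: TfidfVector, b: TfidfVector) -> SimilarityScore:
    """Cosine similarity of two TF-IDF vectors over the same vocabulary.

    Returns 0 if either vector is all-zero (empty document).
    """
    _check_same_vocab(a, b)
    if not a.weights or not b.weights:
        return SimilarityScore(0.0, a.doc_id, b.doc_id)
    # accumulate in sorted term order so the result is exactly symmetric
    shared = sorted(a.weights.keys() & b.weights.keys())
    dot = sum(a.weights[t] * b.weights[t] for t in shared)
    na, nb = a.norm(), b.norm()
    value = dot / (na * nb)
    # guard rounding just past the boundary
    value = min(max(value, 0.0), 1.0)
    return SimilarityScore(value, a.doc_id, b.doc_id)


def aggregate_replicates(vectors: list[TfidfVector], question_id: str = "") -> AggregateVector:
    """Element-wise mean of replicate TF-IDF vectors.

    For term j, ``w_j = (1/N) * sum_i e_ij`` where ``e_ij`` is replicate
    i's weight for term j and N is the number of replicates.
    """
    if not vectors:
        raise ValueError("aggregate_replicates requires at least one vector")
    for v in vectors[1:]:
        _check_same_vocab(vectors[0], v)
    n = len(vectors)
    sums: dict[str, float] = {}
    for v in vectors:
        for t, w in v.weights.items():
            sums[t] = sums.get(t, 0.0) + w
    weights = {t: s / n for t, s in sums.items()}
    return AggregateVector(
        question_id=question_id, weights=weights, n_replicates=n, vocab=vectors[0].vocab
    )


def question_similarity(
    responses: list[TokenSequence],
    reference: TokenSequence,
    vocab: Vocabulary,
    mode: str = "mean_of_scores",
) -> tuple[list[float], float]:
    """Per-replicate similarities to the reference plus a question summary.

    ``mean_of_scores`` (default): the summary is the arithmetic mean of the
    per-replicate cosine similarities.  ``aggregate_vector``: the replicate
    vectors are first averaged element-wise, renormalized, and the summary
    is the cosine of that mean vector with the reference.
    """
    if not responses:
        raise ValueError("question_similarity requires at least one response")
    ref_vec = tfidf_vectorize(reference, vocab)
    rep_vecs = [tfidf_vectorize(r, vocab) for r in responses]
    scores = [cosine_similarity(v, ref_vec).value for v in rep_vecs]
    if mode == "mean_of_scores":
        summary = float(np.mean(scores))
    elif mode == "aggregate_vector":
        agg = aggregate_replicates(rep_vecs)
        norm = math.sqrt(sum(w * w for w in agg.weights.values()))
        if norm == 0.0 or not ref_vec.weights:
            summary = 0.0
        else:
            mean_vec = TfidfVector(
                doc_id="aggregate",
                weights={t: w / norm for t, w in agg.weights.items()},
                normalized=True,
                vocab=vocab,
            )
            summary = cosine_similarity(mean_vec, ref_vec).value
    else:
        raise ValueError(f"unknown summary mode {mode!r}")
    return scores, summary
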