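import numpy as np
import pytest

from concordex.normalize import TokenSequence
from concordex.tfidf import build_vocabulary, tfidf_vectorize


def seq(tokens, source_id=""):
    return TokenSequence(tokens=tuple(tokens), source_id=source_id)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def drug_docs():
    """Two-document pharmacology toy corpus used in hand-worked examples."""
    d1 = seq(["aspirin", "inhibit", "cyclooxygenase"], "d1")
    d2 = seq(["aspirin", "block", "cyclooxygenase", "enzyme"], "d2")
    vocab = build_vocabulary([d1, d2])
    return d1, d2, vocab


@pytest.fixture
def small_corpus_rows():
    """Minimal well-formed corpus: 1 question, 2 model replicates, 1 reference."""
    return [
        {"question_id": "q1", "subject": "pharmacology", "source": "model",
         "replicate_index": 1, "text": "aspirin inhibits cyclooxygenase"},
        {"question_id": "q1", "subject": "pharmacology", "source": "model",
         "replicate_index": 2, "text": "aspirin blocks the cyclooxygenase enzyme"},
        {"question_id": "q1", "subject": "pharmacology", "source": "reference",
         "replicate_index": 1, "text": "aspirin irreversibly inhibits cyclooxygenase enzymes"},
    ]


def dense_tfidf_oracle(docs):
    """Brute-force dense TF-IDF over a token-list corpus.

    Independent of the package's sparse path: builds the full
    document-by-term count matrix with explicit loops, applies
    idf = ln((1+N)/(1+df)) + 1 and row-wise L2 normalization.
    """
    terms = sorted({t for d in docs for t in d})
    n, v = len(docs), len(terms)
    counts = np.zeros((n, v))
    for i, d in enumerate(docs):
        for j, t in enumerate(terms):
            counts[i, j] = sum(1 for x in d if x == t)
    df = np.array([sum(1 for d in docs if t in d) for t in terms], dtype=float)
    idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    W = counts * idf
    norms = np.linalg.norm(W, axis=1)
    nz = norms > 0
    W[nz] = W[nz] / norms[nz, None]
    return terms, W


@pytest.fixture
def vectorize_pair():
    def _pair(tokens_a, tokens_b, extra_docs=()):
        docs = [seq(tokens_a, "a"), seq(tokens_b, "b")] + [
            seq(d, f"x{i}") for i, d in enumerate(extra_docs)
        ]
        vocab = build_vocabulary(docs)
        return tfidf_vectorize(docs[0], vocab), tfidf_vectorize(docs[1], vocab)

    return _pair
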