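"""TF-IDF vectorization, aggregation and cosine similarity.

Dual-route checks: the package's sparse path is compared against a dense
brute-force oracle (conftest) and against scikit-learn's TfidfVectorizer
configured to the same pinned variant.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.feature_extraction.text import TfidfVectorizer

from concordex.tfidf import (
    aggregate_replicates,
    build_vocabulary,
    cosine_similarity,
    question_similarity,
    tfidf_vectorize,
)
from conftest import dense_tfidf_oracle, seq

LN15 = math.log(1.5)


def test_build_vocabulary_counts_and_order():
    vocab = build_vocabulary([seq(["a", "b"]), seq(["b", "c"])])
    assert len(vocab) == 3
    assert vocab.index == {"a": 0, "b": 1, "c": 2}
    assert vocab.df.tolist() == [1, 2, 1]
    assert vocab.n_docs == 2


def test_build_vocabulary_with_empty_doc():
    vocab = build_vocabulary([seq([]), seq(["a"])])
    assert len(vocab) == 1 and vocab.n_docs == 2


def test_build_vocabulary_empty_list_rejected():
    with pytest.raises(ValueError):
        build_vocabulary([])


def test_df_matches_brute_force_on_synthetic_docs(rng):
    docs = [seq([f"t{rng.integers(0, 15)}" for _ in range(12)], f"d{i}") for i in range(20)]
    vocab = build_vocabulary(docs)
    for term, j in vocab.index.items():
        brute = sum(1 for d in docs if term in d.tokens)
        assert vocab.df[j] == brute


def test_single_term_doc_normalizes_to_unit_weight():
    docs = [seq(["a", "a"], "d0"), seq(["b"], "d1")]
    vocab = build_vocabulary(docs)
    vec = tfidf_vectorize(docs[0], vocab)
    assert vec.weights == {"a": 1.0}
    assert vec.normalized


def test_hand_computed_idf_and_cosine(drug_docs):
    d1, d2, vocab = drug_docs
    idf = vocab.idf()
    # shared terms appear in both docs of the 2-doc corpus: ln(3/3)+1 = 1
    assert idf[vocab.index["aspirin"]] == pytest.approx(1.0)
    assert idf[vocab.index["cyclooxygenase"]] == pytest.approx(1.0)
    # unique terms: ln(3/2)+1
    assert idf[vocab.index["inhibit"]] == pytest.approx(LN15 + 1.0)
    v1, v2 = tfidf_vectorize(d1, vocab), tfidf_vectorize(d2, vocab)
    # hand arithmetic: dot = 2 unit-idf shared weights over the two norms
    n1 = math.sqrt(2 + (1 + LN15) ** 2)
    n2 = math.sqrt(2 + 2 * (1 + LN15) ** 2)
    expected = 2 / (n1 * n2)
    assert cosine_similarity(v1, v2).value == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.4112, abs=5e-5)


def test_vector_norm_is_unit(drug_docs):
    d1, _, vocab = drug_docs
    assert tfidf_vectorize(d1, vocab).norm() == pytest.approx(1.0, abs=1e-9)


def test_identical_documents_score_one(vectorize_pair):
    va, vb = vectorize_pair(["renal", "tubule", "sodium"], ["renal", "tubule", "sodium"])
    assert cosine_similarity(va, vb).value == 1.0


def test_disjoint_documents_score_zero(vectorize_pair):
    va, vb = vectorize_pair(["renal", "sodium"], ["hepatic", "bile"])
    assert cosine_similarity(va, vb).value == 0.0


def test_empty_document_scores_zero(vectorize_pair):
    va, vb = vectorize_pair(["renal"], [])
    assert not vb.normalized
    assert cosine_similarity(va, vb).value == 0.0


def test_vocabulary_mismatch_rejected():
    a = tfidf_vectorize(seq(["a"]), build_vocabulary([seq(["a"])]))
    b = tfidf_vectorize(seq(["b"]), build_vocabulary([seq(["b"])]))
    with pytest.raises(ValueError):
        cosine_similarity(a, b)


def test_matches_dense_oracle_and_sklearn(rng):
    token_docs = [
        [f"t{rng.integers(0, 25)}" for _ in range(int(rng.integers(3, 15)))] for _ in range(10)
    ]
    docs = [seq(d, f"d{i}") for i, d in enumerate(token_docs)]
    vocab = build_vocabulary(docs)
    terms, W = dense_tfidf_oracle(token_docs)
    assert terms == vocab.terms
    vecs = [tfidf_vectorize(d, vocab) for d in docs]
    for i, v in enumerate(vecs):
        assert np.allclose(v.dense(), W[i], atol=1e-12)
    # independent route: sklearn with the same pinned variant
    # (feature names come back lexicographically sorted, matching vocab order)
    sk = TfidfVectorizer(analyzer=lambda d: d, norm="l2", smooth_idf=True, sublinear_tf=False)
    SK = sk.fit_transform(token_docs).toarray()
    assert list(sk.get_feature_names_out()) == vocab.terms
    for i, v in enumerate(vecs):
        assert np.allclose(v.dense(), SK[i], atol=1e-12)
    # cosine via oracle matrix
    for i in range(10):
        for j in range(i, 10):
            expected = float(W[i] @ W[j])
            assert cosine_similarity(vecs[i], vecs[j]).value == pytest.approx(expected, abs=1e-12)


def test_aggregate_mean_of_identical_vectors_is_identity(drug_docs):
    d1, _, vocab = drug_docs
    v = tfidf_vectorize(d1, vocab)
    agg = aggregate_replicates([v, v, v])
    assert agg.n_replicates == 3
    for t, w in v.weights.items():
        assert agg.weights[t] == pytest.approx(w, abs=1e-15)


def test_aggregate_two_sparse_vectors():
    from concordex.tfidf import TfidfVector

    vocab = build_vocabulary([seq(["a"]), seq(["b"])])
    va = TfidfVector("x", {"a": 1.0}, True, vocab)
    vb = TfidfVector("y", {"b": 1.0}, True, vocab)
    agg = aggregate_replicates([va, vb])
    assert agg.weights == {"a": 0.5, "b": 0.5}


def test_aggregate_matches_double_loop_oracle(rng):
    docs = [seq([f"t{rng.integers(0, 8)}" for _ in range(10)], f"d{i}") for i in range(10)]
    vocab = build_vocabulary(docs)
    vecs = [tfidf_vectorize(d, vocab) for d in docs]
    agg = aggregate_replicates(vecs)
    for term in vocab.index:
        expected = sum(v.weights.get(term, 0.0) for v in vecs) / len(vecs)
        assert agg.weights.get(term, 0.0) == pytest.approx(expected, abs=1e-12)


def test_aggregate_empty_list_rejected():
    with pytest.raises(ValueError):
        aggregate_replicates([])


def test_question_similarity_modes(rng):
    ref = seq(["renal", "sodium", "channel", "block"], "ref")
    reps = [seq(["renal", "sodium", f"extra{i}"], f"r{i}") for i in range(5)]
    vocab = build_vocabulary([ref] + reps)
    ref_vec = tfidf_vectorize(ref, vocab)
    hand = [cosine_similarity(tfidf_vectorize(r, vocab), ref_vec).value for r in reps]
    scores, summary = question_similarity(reps, ref, vocab)
    assert scores == pytest.approx(hand)
    assert summary == pytest.approx(sum(hand) / 5, abs=1e-12)
    _, s_agg = question_similarity(reps, ref, vocab, mode="aggregate_vector")
    assert 0.0 <= s_agg <= 1.0
    _, s_same = question_similarity([ref, ref], ref, vocab, mode="aggregate_vector")
    assert s_same == pytest.approx(1.0, abs=1e-12)


token_lists = st.lists(
    st.sampled_from(["alpha", "beta", "gamma", "delta", "renal", "hepatic"]),
    min_size=0, max_size=12,
)


@settings(max_examples=100, deadline=None)
@given(token_lists, token_lists)
def test_cosine_symmetry_and_bounds(ta, tb):
    docs = [seq(ta, "a"), seq(tb, "b"), seq(["padding", "doc"], "c")]
    vocab = build_vocabulary(docs)
    va, vb = tfidf_vectorize(docs[0], vocab), tfidf_vectorize(docs[1], vocab)
    sab = cosine_similarity(va, vb).value
    sba = cosine_similarity(vb, va).value
    assert sab == sba
    assert 0.0 <= sab <= 1.0


@settings(max_examples=50, deadline=None)
@given(token_lists.filter(lambda t: len(t) > 0), st.integers(min_value=2, max_value=5))
def test_repeating_a_document_leaves_similarity_unchanged(tokens, k):
    other = ["renal", "hepatic", "alpha"]
    docs = [seq(tokens, "a"), seq(other, "b")]
    vocab = build_vocabulary(docs)
    base = cosine_similarity(tfidf_vectorize(docs[0], vocab), tfidf_vectorize(docs[1], vocab)).value
    repeated = seq(list(tokens) * k, "a_rep")
    rep = cosine_similarity(tfidf_vectorize(repeated, vocab), tfidf_vectorize(docs[1], vocab)).value
    assert rep == pytest.approx(base, abs=1e-9)
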