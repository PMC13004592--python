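"""Randomized-text null model: unigram estimation, sampling, significance."""

import numpy as np
import pytest

from concordex.nullmodel import (
    DEFAULT_NULL_SAMPLES,
    build_null,
    estimate_unigram,
    random_text,
)
from concordex.nullmodel import test_significance as assess_significance
from concordex.tfidf import build_vocabulary, cosine_similarity, tfidf_vectorize
from conftest import seq


def test_estimate_unigram_relative_frequencies():
    dist = estimate_unigram([seq(["a", "a", "b"])])
    assert dist.as_dict() == pytest.approx({"a": 2 / 3, "b": 1 / 3})
    dist2 = estimate_unigram([seq(["a"]), seq(["b"])])
    assert dist2.as_dict() == pytest.approx({"a": 0.5, "b": 0.5})


def test_estimate_unigram_matches_counter_oracle(rng):
    docs = [seq([f"t{rng.integers(0, 9)}" for _ in range(20)], f"d{i}") for i in range(10)]
    dist = estimate_unigram(docs)
    from collections import Counter

    tally = Counter(t for d in docs for t in d.tokens)
    total = sum(tally.values())
    for term, p in dist.as_dict().items():
        assert p == pytest.approx(tally[term] / total)
    assert np.isclose(dist.probs.sum(), 1.0, atol=1e-9)


def test_estimate_unigram_all_empty_rejected():
    with pytest.raises(ValueError):
        estimate_unigram([seq([])])


def test_random_text_degenerate_distribution(rng):
    dist = estimate_unigram([seq(["a"])])
    assert random_text(4, dist, rng).tokens == ("a", "a", "a", "a")


def test_random_text_seed_determinism():
    dist = estimate_unigram([seq(["a", "b", "c", "c"])])
    t1 = random_text(50, dist, np.random.default_rng(9))
    t2 = random_text(50, dist, np.random.default_rng(9))
    assert t1.tokens == t2.tokens


def test_random_text_length_validation(rng):
    dist = estimate_unigram([seq(["a"])])
    with pytest.raises(ValueError):
        random_text(0, dist, rng)


def test_random_text_frequencies_near_expectation(rng):
    # binomial bound: with p=0.5 and n=10000, 3 sigma is ~0.015
    dist = estimate_unigram([seq(["a"]), seq(["b"])])
    text = random_text(10000, dist, rng)
    frac_a = sum(1 for t in text.tokens if t == "a") / 10000
    assert 0.48 <= frac_a <= 0.52


def test_build_null_default_B_is_1000(rng):
    ref = seq(["a", "b", "a"], "ref")
    vocab = build_vocabulary([ref, seq(["a", "c"], "d1")])
    dist = estimate_unigram([ref])
    null = build_null(ref, vocab, dist, rng=rng)
    assert null.B == DEFAULT_NULL_SAMPLES == 1000


def test_build_null_degenerate_dist_matches_hand_tfidf(rng):
    # distribution concentrated on one reference term: the forced random
    # text is a run of that term, whose score the sparse path reproduces
    ref = seq(["a", "b"], "ref")
    other = seq(["b", "c"], "d1")
    vocab = build_vocabulary([ref, other])
    dist = estimate_unigram([seq(["a"])])
    null = build_null(ref, vocab, dist, B=1, rng=rng)
    forced = seq(["a"] * 2, "forced")
    expected = cosine_similarity(tfidf_vectorize(forced, vocab), tfidf_vectorize(ref, vocab)).value
    assert null.scores[0] == pytest.approx(expected, abs=1e-12)


def test_build_null_disjoint_support_scores_zero(rng):
    ref = seq(["a", "b"], "ref")
    vocab = build_vocabulary([ref, seq(["c", "d"], "d1")])
    dist = estimate_unigram([seq(["c", "d"])])
    null = build_null(ref, vocab, dist, B=20, rng=rng)
    assert np.all(null.scores == 0.0)


def test_build_null_count_path_equals_sequence_path():
    # TF-IDF depends only on term counts: scoring a sampled token sequence
    # must equal scoring its count vector, so the multinomial fast path is
    # exchangeable with literal text sampling
    ref = seq(["a", "b", "c", "a"], "ref")
    vocab = build_vocabulary([ref, seq(["b", "d"], "d1")])
    dist = estimate_unigram([ref])
    text = random_text(30, dist, np.random.default_rng(4))
    direct = cosine_similarity(tfidf_vectorize(text, vocab), tfidf_vectorize(ref, vocab)).value
    # same counts, shuffled order
    shuffled = seq(tuple(sorted(text.tokens)), "shuffled")
    assert cosine_similarity(
        tfidf_vectorize(shuffled, vocab), tfidf_vectorize(ref, vocab)
    ).value == pytest.approx(direct, abs=1e-12)


def test_build_null_reproducible_with_seed():
    ref = seq(["a", "b", "c", "a", "b"], "ref")
    vocab = build_vocabulary([ref, seq(["a", "c"], "d1")])
    dist = estimate_unigram([ref])
    n1 = build_null(ref, vocab, dist, B=50, rng=np.random.default_rng(7), lengths=[5, 5, 5])
    n2 = build_null(ref, vocab, dist, B=50, rng=np.random.default_rng(7), lengths=[5, 5, 5])
    assert np.array_equal(n1.scores, n2.scores)


def test_significance_extremes():
    from concordex.nullmodel import NullDistribution

    null = NullDistribution(scores=np.linspace(0.0, 0.5, 100))
    above = assess_significance(0.9, null)
    assert above.significant
    assert above.p_value == pytest.approx(1 / 101)
    below = assess_significance(0.0, null)
    assert not below.significant
    assert below.p_value == 1.0


def test_threshold_is_linear_interpolated_95th_percentile(rng):
    from concordex.nullmodel import NullDistribution

    scores = rng.random(1000) * 0.4
    null = NullDistribution(scores=scores)
    res = assess_significance(0.2, null)
    # independent computation: sort and interpolate between closest ranks
    s = np.sort(scores)
    h = 0.95 * (len(s) - 1)
    lo, hi = int(np.floor(h)), int(np.ceil(h))
    expected = s[lo] + (h - lo) * (s[hi] - s[lo])
    assert res.threshold_95 == pytest.approx(expected, abs=1e-12)
    assert res.significant == (0.2 > expected)


def test_p_value_monotone_in_observed(rng):
    from concordex.nullmodel import NullDistribution

    null = NullDistribution(scores=rng.random(500))
    obs = np.sort(rng.random(50))
    ps = [assess_significance(o, null).p_value for o in obs]
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


def test_significance_consistent_with_percentile_rule(rng):
    from concordex.nullmodel import NullDistribution

    scores = rng.random(1000)
    null = NullDistribution(scores=scores)
    for obs in rng.random(20):
        res = assess_significance(obs, null)
        if res.significant:
            assert res.p_value < 0.05 + 1 / (len(scores) + 1) + 1e-12
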