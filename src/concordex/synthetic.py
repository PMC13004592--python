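"""Synthetic study corpora with known ground truth.

Real study data — question-bank items, live model answers, curated
reference article sections — cannot be redistributed, so every pipeline
stage is exercised on generated corpora whose lexical overlap with the
reference is controlled.

The generator emulates only the bag-of-words statistics the method
consumes, not prose.  Each question's reference is drawn from a
question-specific Zipf-weighted distribution over a shared vocabulary
(natural-language term frequencies are heavy-tailed, and TF-IDF behaviour
is sensitive to that).  Each model-response token is then drawn, with
probability ``rho``, from the reference's empirical token distribution and
otherwise from a disjoint distractor vocabulary's Zipf distribution —
so ``rho`` is the expected fraction of on-topic tokens and subject-level
mean similarity is monotone in it.

Pseudo-words are consonant-only lowercase strings: they contain no digits,
match no stop word, and are fixed points of the lemmatizer's suffix rules,
so generated texts survive normalization verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .corpus import QuestionRecord, ResponseRecord, StudyCorpus

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_null_corpus",
    "DEFAULT_SUBJECTS",
]

# The five preclinical subject areas of the study design, paired with
# default on-topic token fractions spanning weak to moderate overlap.
DEFAULT_SUBJECTS: list[tuple[str, float]] = [
    ("biochemistry", 0.1),
    ("immunology", 0.2),
    ("microbiology", 0.3),
    ("pathology", 0.4),
    ("pharmacology", 0.5),
]


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic corpus generator.

    ``subjects`` pairs each subject label with its overlap parameter rho in
    [0, 1].  ``replicates`` is the number of stochastic model responses per
    question (the study design collects 10).  Lengths are in normalized
    tokens.
    """

    subjects: list[tuple[str, float]] = Field(default_factory=lambda: list(DEFAULT_SUBJECTS))
    questions_per_subject: int = Field(default=30, ge=1)
    replicates: int = Field(default=10, ge=1)
    reference_length: int = Field(default=120, ge=1)
    response_length: int = Field(default=80, ge=1)
    shared_vocab_size: int = Field(default=250, ge=1)
    distractor_vocab_size: int = Field(default=250, ge=1)
    zipf_exponent: float = Field(default=1.0, ge=0.0)
    seed: int = 0

    @field_validator("subjects")
    @classmethod
    def _check_subjects(cls, v):
        if not v:
            raise ValueError("subjects: at least one (label, rho) pair required")
        labels = [s for s, _ in v]
        if len(set(labels)) != len(labels):
            raise ValueError("subjects: labels must be unique")
        for label, rho in v:
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"subjects: rho for {label!r} must lie in [0, 1], got {rho}")
        return v


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    question_rho: dict[str, float]
    subject_rho: dict[str, float]

    @property
    def expected_ranking(self) -> list[str]:
        """Subjects ordered by increasing rho (expected similarity order)."""
        return [s for s, _ in sorted(self.subject_rho.items(), key=lambda kv: (kv[1], kv[0]))]


# Consonant "digits": no vowels, so no pseudo-word can end in -s, -es,
# -ies, -ed or -ing, match a stop word, or contain a numeral.
_CONSONANTS = "bcdfghjklm"


def _pseudo_word(prefix: str, i: int, width: int = 4) -> str:
    digits = []
    for _ in range(width):
        digits.append(_CONSONANTS[i % len(_CONSONANTS)])
        i //= len(_CONSONANTS)
    return prefix + "".join(reversed(digits))


def _make_vocab(prefix: str, size: int) -> list[str]:
    width = 4
    while len(_CONSONANTS) ** width < size:
        width += 1
    return [_pseudo_word(prefix, i, width) for i in range(size)]


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, size + 1, dtype=float) ** exponent
    return w / w.sum()


def _draw_text(rng: np.random.Generator, words: list[str], probs: np.ndarray, length: int) -> list[str]:
    idx = rng.choice(len(words), size=length, p=probs)
    return [words[i] for i in idx]


def _question_ids(config: SyntheticConfig) -> list[tuple[str, str]]:
    out = []
    for label, _ in config.subjects:
        for q in range(1, config.questions_per_subject + 1):
            out.append((f"{label}-q{q:03d}", label))
    return out


def generate_corpus(config: SyntheticConfig) -> tuple[StudyCorpus, GroundTruth]:
    """Generate a corpus with controlled response/reference overlap.

    Returns the corpus together with the :class:`GroundTruth` describing
    the overlap parameter behind every question.
    """
    rng = np.random.default_rng(config.seed)
    shared = _make_vocab("z", config.shared_vocab_size)
    distractor = _make_vocab("q", config.distractor_vocab_size)
    zipf_shared = _zipf_probs(config.shared_vocab_size, config.zipf_exponent)
    zipf_distractor = _zipf_probs(config.distractor_vocab_size, config.zipf_exponent)

    rho_of = dict(config.subjects)
    questions: list[QuestionRecord] = []
    responses: list[ResponseRecord] = []
    question_rho: dict[str, float] = {}

    for qid, label in _question_ids(config):
        rho = rho_of[label]
        # question-specific topic: Zipf weights assigned to a shuffled
        # ordering of the shared vocabulary
        perm = rng.permutation(config.shared_vocab_size)
        ref_probs = zipf_shared[np.argsort(perm)]
        ref_tokens = _draw_text(rng, shared, ref_probs, config.reference_length)

        # empirical distribution of the realized reference
        uniq, counts = np.unique(ref_tokens, return_counts=True)
        emp_probs = counts / counts.sum()

        questions.append(QuestionRecord(question_id=qid, subject=label, text=f"question {qid}"))
        question_rho[qid] = rho
        responses.append(
            ResponseRecord(qid, "reference", 1, " ".join(ref_tokens))
        )
        for k in range(1, config.replicates + 1):
            on_topic = rng.random(config.response_length) < rho
            tokens = np.where(
                on_topic,
                np.array(_draw_text(rng, list(uniq), emp_probs, config.response_length)),
                np.array(_draw_text(rng, distractor, zipf_distractor, config.response_length)),
            )
            responses.append(ResponseRecord(qid, "model", k, " ".join(tokens.tolist())))

    corpus = StudyCorpus(questions=tuple(questions), responses=tuple(responses))
    truth = GroundTruth(question_rho=question_rho, subject_rho=dict(config.subjects))
    return corpus, truth


def generate_null_corpus(config: SyntheticConfig) -> StudyCorpus:
    """Generate a corpus in which every response is null random text.

    References are produced exactly as in :func:`generate_corpus`; model
    responses are then drawn i.i.d. from the unigram distribution pooled
    over *all* generated references — the same process the null model's
    random-text resampling uses — so the significance rule's null
    hypothesis holds exactly and its rejection rate measures type-I error.
    """
    rng = np.random.default_rng(config.seed)
    shared = _make_vocab("z", config.shared_vocab_size)
    zipf_shared = _zipf_probs(config.shared_vocab_size, config.zipf_exponent)

    refs: dict[str, list[str]] = {}
    ids = _question_ids(config)
    for qid, _label in ids:
        perm = rng.permutation(config.shared_vocab_size)
        ref_probs = zipf_shared[np.argsort(perm)]
        refs[qid] = _draw_text(rng, shared, ref_probs, config.reference_length)

    pooled_counts: dict[str, int] = {}
    for tokens in refs.values():
        for t in tokens:
            pooled_counts[t] = pooled_counts.get(t, 0) + 1
    pool_terms = sorted(pooled_counts)
    pool_probs = np.array([pooled_counts[t] for t in pool_terms], dtype=float)
    pool_probs /= pool_probs.sum()

    questions: list[QuestionRecord] = []
    responses: list[ResponseRecord] = []
    for qid, label in ids:
        questions.append(QuestionRecord(question_id=qid, subject=label, text=f"question {qid}"))
        responses.append(ResponseRecord(qid, "reference", 1, " ".join(refs[qid])))
        for k in range(1, config.replicates + 1):
            tokens = _draw_text(rng, pool_terms, pool_probs, config.response_length)
            responses.append(ResponseRecord(qid, "model", k, " ".join(tokens)))
    return StudyCorpus(questions=tuple(questions), responses=tuple(responses))
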