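"""Subject-level aggregation, replicate sensitivity analysis, and 2-D projection.

Per-question results (mean similarity plus significance call) roll up into
per-subject summaries: the mean and sample standard deviation of the
question-level mean similarities, and counts of significant vs
non-significant questions.  A sensitivity table reports how the summary
would change had only the first replicate, or the per-question median,
maximum or minimum replicate similarity, been used — a check that
conclusions are not artifacts of the replicate sampling.  TF-IDF vectors
can additionally be projected onto their top two principal components for
scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tfidf import TfidfVector

__all__ = [
    "QuestionResult",
    "SubjectSummary",
    "SensitivityRow",
    "summarize_subject",
    "summarize_all_subjects",
    "sensitivity",
    "sensitivity_table",
    "count_table",
    "project_2d",
]


@dataclass(frozen=True)
class QuestionResult:
    question_id: str
    subject: str
    per_replicate_scores: tuple[float, ...]
    mean_similarity: float
    p_value: float
    threshold_95: float
    significant: bool


@dataclass(frozen=True)
class SubjectSummary:
    subject: str
    n_questions: int
    mean: float
    sd: float
    n_significant: int
    n_not_significant: int


@dataclass(frozen=True)
class SensitivityRow:
    subject: str
    first: float
    median: float
    sd: float
    maximum: float
    minimum: float


def _of_subject(results: list[QuestionResult], subject: str) -> list[QuestionResult]:
    sub = [r for r in results if r.subject == subject]
    if not sub:
        raise ValueError(f"no results carry subject {subject!r}")
    return sub


def summarize_subject(results: list[QuestionResult], subject: str) -> SubjectSummary:
    """Mean/SD of question-level mean similarities within one subject.

    SD is the sample standard deviation (n-1 denominator); a single
    question yields SD 0.
    """
    sub = _of_subject(results, subject)
    means = np.array([r.mean_similarity for r in sub])
    n_sig = sum(r.significant for r in sub)
    return SubjectSummary(
        subject=subject,
        n_questions=len(sub),
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)) if len(sub) > 1 else 0.0,
        n_significant=int(n_sig),
        n_not_significant=len(sub) - int(n_sig),
    )


def summarize_all_subjects(results: list[QuestionResult]) -> list[SubjectSummary]:
    subjects = sorted({r.subject for r in results})
    return [summarize_subject(results, s) for s in subjects]


def sensitivity(results: list[QuestionResult], subject: str) -> SensitivityRow:
    """Replicate-subset sensitivity for one subject.

    Per question, take the first replicate's score and the median, maximum
    and minimum across replicates; the row reports the subject-level mean
    of each and the SD (across questions) of the median-based scores.
    """
    sub = _of_subject(results, subject)
    firsts, medians, maxima, minima = [], [], [], []
    for r in sub:
        scores = np.array(r.per_replicate_scores)
        firsts.append(scores[0])
        medians.append(float(np.median(scores)))
        maxima.append(float(scores.max()))
        minima.append(float(scores.min()))
    medians_arr = np.array(medians)
    return SensitivityRow(
        subject=subject,
        first=float(np.mean(firsts)),
        median=float(medians_arr.mean()),
        sd=float(medians_arr.std(ddof=1)) if len(sub) > 1 else 0.0,
        maximum=float(np.mean(maxima)),
        minimum=float(np.mean(minima)),
    )


def sensitivity_table(results: list[QuestionResult]) -> pd.DataFrame:
    subjects = sorted({r.subject for r in results})
    rows = [sensitivity(results, s) for s in subjects]
    return pd.DataFrame(
        [
            {
                "subject": r.subject,
                "first": r.first,
                "median": r.median,
                "sd": r.sd,
                "maximum": r.maximum,
                "minimum": r.minimum,
            }
            for r in rows
        ]
    )


def count_table(results: list[QuestionResult]) -> pd.DataFrame:
    """Per-subject counts and percentages of significant questions.

    Includes an ``overall`` row; percentages are computed from the counts
    and printed to one decimal in the CSV output.
    """
    if not results:
        raise ValueError("results is empty")
    rows = []
    subjects = sorted({r.subject for r in results})
    for subject in subjects + ["overall"]:
        sub = results if subject == "overall" else [r for r in results if r.subject == subject]
        n = len(sub)
        n_sig = sum(r.significant for r in sub)
        rows.append(
            {
                "subject": subject,
                "n_questions": n,
                "n_significant": n_sig,
                "n_not_significant": n - n_sig,
                "pct_significant": round(100.0 * n_sig / n, 1),
                "pct_not_significant": round(100.0 * (n - n_sig) / n, 1),
            }
        )
    return pd.DataFrame(rows)


def project_2d(vectors: list[TfidfVector]) -> dict[str, tuple[float, float]]:
    """Top-2 principal-component coordinates of TF-IDF vectors.

    The document-by-term weight matrix is column-centered and decomposed by
    SVD; coordinates along the first component carry at least as much
    variance as along the second.  Each component's sign is fixed so that
    its largest-magnitude loading is positive, making the output
    deterministic.
    """
    if len(vectors) < 3:
        raise ValueError("projection requires at least 3 documents")
    X = np.vstack([v.dense() for v in vectors])
    Xc = X - X.mean(axis=0)
    # economy SVD: principal axes are rows of Vt
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = U[:, :2] * S[:2]
    for j in range(min(2, Vt.shape[0])):
        load = Vt[j]
        k = int(np.argmax(np.abs(load)))
        if load[k] < 0:
            coords[:, j] = -coords[:, j]
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(len(vectors))])
    return {
        v.doc_id or f"doc{i}": (float(coords[i, 0]), float(coords[i, 1]))
        for i, v in enumerate(vectors)
    }
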