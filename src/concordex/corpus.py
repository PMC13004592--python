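"""Reading and writing study corpora and result tables.

A study corpus couples each question with one curated reference text and
K stochastic model-response replicates.  On disk a corpus is a flat table —
one response per row — in CSV or JSON, with columns/keys::

    question_id, subject, source, replicate_index, text

``source`` is ``model`` or ``reference``; reference rows always carry
``replicate_index`` 1 (the reference is collected once).  The question
table is implied by the distinct (question_id, subject) pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

__all__ = [
    "CorpusFormatError",
    "CorpusIntegrityError",
    "QuestionRecord",
    "ResponseRecord",
    "StudyCorpus",
    "read_corpus",
    "write_corpus",
    "write_results",
]

_COLUMNS = ["question_id", "subject", "source", "replicate_index", "text"]

RESULT_COLUMNS = [
    "question_id", "subject", "n_replicates", "mean_similarity",
    "p_value", "threshold_95", "significant",
]
SUBJECT_COLUMNS = [
    "subject", "n_questions", "mean", "sd", "n_significant", "n_not_significant",
]


class CorpusFormatError(ValueError):
    """The file does not conform to the documented column/field layout."""


class CorpusIntegrityError(ValueError):
    """The rows parse but violate a corpus invariant."""


@dataclass(frozen=True)
class QuestionRecord:
    question_id: str
    subject: str
    text: str = ""


@dataclass(frozen=True)
class ResponseRecord:
    question_id: str
    source: Literal["model", "reference"]
    replicate_index: int
    text: str


@dataclass(frozen=True)
class StudyCorpus:
    """All questions plus their reference and model-response texts."""

    questions: tuple[QuestionRecord, ...]
    responses: tuple[ResponseRecord, ...]

    def question_ids(self) -> list[str]:
        return [q.question_id for q in self.questions]

    def subject_of(self, question_id: str) -> str:
        for q in self.questions:
            if q.question_id == question_id:
                return q.subject
        raise KeyError(question_id)

    def reference(self, question_id: str) -> ResponseRecord:
        for r in self.responses:
            if r.question_id == question_id and r.source == "reference":
                return r
        raise KeyError(f"no reference for question {question_id!r}")

    def replicates(self, question_id: str) -> list[ResponseRecord]:
        reps = [
            r for r in self.responses
            if r.question_id == question_id and r.source == "model"
        ]
        return sorted(reps, key=lambda r: r.replicate_index)


def _validate(df: pd.DataFrame) -> StudyCorpus:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"missing required column(s): {', '.join(missing)}")
    bad_source = set(df["source"].unique()) - {"model", "reference"}
    if bad_source:
        raise CorpusFormatError(f"invalid source value(s): {sorted(bad_source)}")
    if df["text"].isna().any() or (df["text"].astype(str).str.len() == 0).any():
        raise CorpusFormatError("empty text field")

    df = df.copy()
    df["replicate_index"] = df["replicate_index"].astype(int)

    dup = df.duplicated(subset=["question_id", "source", "replicate_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise CorpusIntegrityError(
            f"duplicate ({row.question_id!r}, {row.source!r}, {row.replicate_index})"
        )

    # subject must be consistent within a question
    nsubj = df.groupby("question_id")["subject"].nunique()
    incoherent = nsubj[nsubj > 1]
    if not incoherent.empty:
        raise CorpusIntegrityError(
            f"question {incoherent.index[0]!r} carries multiple subject labels"
        )

    questions, responses = [], []
    for qid, grp in df.groupby("question_id", sort=False):
        refs = grp[grp["source"] == "reference"]
        models = grp[grp["source"] == "model"]
        if len(refs) != 1:
            raise CorpusIntegrityError(
                f"question {qid!r} has {len(refs)} reference rows (exactly 1 required)"
            )
        if int(refs.iloc[0]["replicate_index"]) != 1:
            raise CorpusIntegrityError(
                f"question {qid!r}: reference rows must carry replicate_index 1"
            )
        if models.empty:
            raise CorpusIntegrityError(f"question {qid!r} has no model responses")
        idx = sorted(models["replicate_index"].tolist())
        if idx != list(range(1, len(idx) + 1)):
            raise CorpusIntegrityError(
                f"question {qid!r}: replicate_index values {idx} are not 1..K contiguous"
            )
        questions.append(QuestionRecord(question_id=str(qid), subject=str(grp.iloc[0]["subject"])))
        for row in grp.itertuples(index=False):
            responses.append(
                ResponseRecord(
                    question_id=str(row.question_id),
                    source=row.source,
                    replicate_index=int(row.replicate_index),
                    text=str(row.text),
                )
            )
    return StudyCorpus(questions=tuple(questions), responses=tuple(responses))


def read_corpus(path: str | Path, format: str | None = None) -> StudyCorpus:
    """Read a study corpus from CSV or JSON.

    ``format`` defaults to the file extension.  Raises
    :class:`CorpusFormatError` for layout problems and
    :class:`CorpusIntegrityError` for invariant violations, naming the
    offending column or question.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"question_id": str, "subject": str, "text": str})
    elif fmt == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(records, list):
            raise CorpusFormatError("JSON corpus must be a list of objects")
        df = pd.DataFrame.from_records(records)
    else:
        raise CorpusFormatError(f"unknown corpus format {fmt!r} (expected csv or json)")
    if df.empty:
        raise CorpusFormatError("corpus file contains no rows")
    return _validate(df)


def write_corpus(corpus: StudyCorpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus in the flat one-response-per-row layout."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    subj = {q.question_id: q.subject for q in corpus.questions}
    rows = [
        {
            "question_id": r.question_id,
            "subject": subj[r.question_id],
            "source": r.source,
            "replicate_index": r.replicate_index,
            "text": r.text,
        }
        for r in corpus.responses
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=1), encoding="utf-8")
    else:
        raise CorpusFormatError(f"unknown corpus format {fmt!r} (expected csv or json)")


def write_results(question_results, subject_summaries, out_dir: str | Path) -> dict[str, Path]:
    """Write per-question results and subject summaries as CSV.

    Accepts the QuestionResult and SubjectSummary records produced by
    :mod:`concordex.report`.  Returns the paths written
    (``results.csv`` and ``subjects.csv`` under ``out_dir``).
    """
    if not question_results:
        raise ValueError("question_results is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    qdf = pd.DataFrame(
        [
            {
                "question_id": r.question_id,
                "subject": r.subject,
                "n_replicates": len(r.per_replicate_scores),
                "mean_similarity": r.mean_similarity,
                "p_value": r.p_value,
                "threshold_95": r.threshold_95,
                "significant": r.significant,
            }
            for r in question_results
        ],
        columns=RESULT_COLUMNS,
    )
    sdf = pd.DataFrame(
        [
            {
                "subject": s.subject,
                "n_questions": s.n_questions,
                "mean": s.mean,
                "sd": s.sd,
                "n_significant": s.n_significant,
                "n_not_significant": s.n_not_significant,
            }
            for s in subject_summaries
        ],
        columns=SUBJECT_COLUMNS,
    )
    paths = {
        "results": out_dir / "results.csv",
        "subjects": out_dir / "subjects.csv",
    }
    # repr-roundtrip float formatting so read-back equals written values
    qdf.to_csv(paths["results"], index=False)
    sdf.to_csv(paths["subjects"], index=False)
    return paths
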