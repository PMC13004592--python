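"""End-to-end orchestration: corpus -> normalized tokens -> TF-IDF ->
per-question similarity + null-model significance -> summary tables.

One run builds a single global vocabulary over every document it analyses
(all selected model replicates plus all references), estimates the pooled
reference unigram distribution, and then processes questions independently
with per-question RNG streams spawned from the master seed, so results are
reproducible bit-for-bit and independent of question order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .corpus import StudyCorpus, read_corpus, write_results
from .normalize import NormalizationConfig, TokenSequence, normalize
from .nullmodel import DEFAULT_NULL_SAMPLES, build_null, estimate_unigram, test_significance
from .report import (
    QuestionResult,
    SubjectSummary,
    count_table,
    project_2d,
    sensitivity_table,
    summarize_all_subjects,
)
from .tfidf import build_vocabulary, question_similarity, tfidf_vectorize

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


class RunConfig(BaseModel):
    """Configuration of a full analysis run.

    ``replicate_mode="first_n"`` restricts each question to its first
    ``first_n`` replicates (the study design collects 10 responses but
    compares 5); ``"all"`` uses every replicate present.
    """

    normalization: NormalizationConfig = Field(default_factory=NormalizationConfig)
    null_samples: int = Field(default=DEFAULT_NULL_SAMPLES, ge=1)
    replicate_mode: Literal["all", "first_n"] = "all"
    first_n: int = Field(default=5, ge=1)
    summary_mode: Literal["mean_of_scores", "aggregate_vector"] = "mean_of_scores"
    seed: int = 0
    project: bool = True


@dataclass
class PipelineResult:
    question_results: list[QuestionResult]
    subject_summaries: list[SubjectSummary]
    sensitivity: pd.DataFrame
    counts: pd.DataFrame
    projection: dict[str, tuple[float, float]] | None
    manifest: dict


def _select_replicates(corpus: StudyCorpus, config: RunConfig):
    for q in corpus.questions:
        reps = corpus.replicates(q.question_id)
        if config.replicate_mode == "first_n":
            reps = reps[: config.first_n]
        yield q, reps


def run_pipeline(
    corpus: StudyCorpus | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full concordance analysis.

    ``corpus`` may be a :class:`StudyCorpus` or a path to a corpus file.
    When ``out_dir`` is given, writes results.csv, subjects.csv,
    sensitivity.csv, counts.csv, projection.csv and manifest.json there;
    on any failure, partially written outputs are removed.
    """
    config = config or RunConfig()
    checksum = None
    if not isinstance(corpus, StudyCorpus):
        path = Path(corpus)
        checksum = hashlib.sha256(path.read_bytes()).hexdigest()
        corpus = read_corpus(path)

    ncfg = config.normalization
    norm_refs: dict[str, TokenSequence] = {}
    norm_reps: dict[str, list[TokenSequence]] = {}
    selected = list(_select_replicates(corpus, config))
    for q, reps in selected:
        qid = q.question_id
        ref = corpus.reference(qid)
        norm_refs[qid] = normalize(ref.text, ncfg, source_id=f"{qid}:ref")
        norm_reps[qid] = [
            normalize(r.text, ncfg, source_id=f"{qid}:rep{r.replicate_index}") for r in reps
        ]

    all_docs = list(norm_refs.values()) + [d for docs in norm_reps.values() for d in docs]
    vocab = build_vocabulary(all_docs)
    unigram = estimate_unigram(list(norm_refs.values()))

    master = np.random.SeedSequence(config.seed)
    child_seeds = master.spawn(len(selected))

    question_results: list[QuestionResult] = []
    for (q, _reps), child in zip(selected, child_seeds):
        qid = q.question_id
        reference = norm_refs[qid]
        replicates = norm_reps[qid]
        scores, summary = question_similarity(replicates, reference, vocab, mode=config.summary_mode)
        rng = np.random.default_rng(child)
        null = build_null(
            reference,
            vocab,
            unigram,
            B=config.null_samples,
            rng=rng,
            lengths=[max(len(r), 1) for r in replicates],
        )
        sig = test_significance(summary, null)
        question_results.append(
            QuestionResult(
                question_id=qid,
                subject=q.subject,
                per_replicate_scores=tuple(scores),
                mean_similarity=summary,
                p_value=sig.p_value,
                threshold_95=sig.threshold_95,
                significant=sig.significant,
            )
        )

    subject_summaries = summarize_all_subjects(question_results)
    sens = sensitivity_table(question_results)
    counts = count_table(question_results)

    projection = None
    if config.project:
        vectors = [tfidf_vectorize(norm_refs[q.question_id], vocab) for q, _ in selected]
        vectors += [
            tfidf_vectorize(d, vocab) for q, _ in selected for d in norm_reps[q.question_id]
        ]
        if len(vectors) >= 3:
            projection = project_2d(vectors)

    manifest = {
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "n_questions": len(question_results),
        "n_vocabulary_terms": len(vocab),
        "input_sha256": checksum,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    result = PipelineResult(
        question_results=question_results,
        subject_summaries=subject_summaries,
        sensitivity=sens,
        counts=counts,
        projection=projection,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        paths = write_results(result.question_results, result.subject_summaries, out_dir)
        written.extend(paths.values())

        p = out_dir / "sensitivity.csv"
        result.sensitivity.to_csv(p, index=False)
        written.append(p)

        p = out_dir / "counts.csv"
        counts = result.counts.copy()
        for col in ("pct_significant", "pct_not_significant"):
            counts[col] = counts[col].map(lambda v: f"{v:.1f}")
        counts.to_csv(p, index=False)
        written.append(p)

        if result.projection is not None:
            p = out_dir / "projection.csv"
            rows = [
                {"doc_id": d, "x": xy[0], "y": xy[1]} for d, xy in result.projection.items()
            ]
            pd.DataFrame(rows).to_csv(p, index=False)
            written.append(p)

        p = out_dir / "manifest.json"
        p.write_text(json.dumps(result.manifest, indent=1), encoding="utf-8")
        written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
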