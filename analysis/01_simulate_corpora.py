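"""Generate the study corpora used by the downstream analysis steps.

Writes two corpora under scratch/analysis_data/:

* corpus.csv — 5 subjects x 30 questions x 10 replicates with subject
  overlap rho = 0.1 .. 0.5 (the study-scale synthetic stand-in for a
  150-question bank), plus ground_truth.json recording rho per question.
* null_corpus.csv — same shape but every response is null random text,
  used by the type-I-error calibration step.
"""

import json
from pathlib import Path

from concordex.corpus import write_corpus
from concordex.synthetic import SyntheticConfig, generate_corpus, generate_null_corpus

OUT = Path(__file__).resolve().parent.parent / "scratch" / "analysis_data"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)  # defaults: 5 subjects, Q=30, K=10
    corpus, truth = generate_corpus(cfg)
    write_corpus(corpus, OUT / "corpus.csv")
    (OUT / "ground_truth.json").write_text(
        json.dumps({"subject_rho": truth.subject_rho,
                    "expected_ranking": truth.expected_ranking}, indent=1)
    )
    print(f"corpus.csv: {len(corpus.questions)} questions, {len(corpus.responses)} responses")

    null_corpus = generate_null_corpus(cfg)
    write_corpus(null_corpus, OUT / "null_corpus.csv")
    print(f"null_corpus.csv: {len(null_corpus.questions)} questions")
    print(f"expected subject ranking by overlap: {truth.expected_ranking}")


if __name__ == "__main__":
    main()
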