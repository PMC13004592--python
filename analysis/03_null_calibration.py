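"""Type-I-error calibration of the significance rule.

Runs the pipeline over the null corpus (every response is random text from
the pooled reference word distribution) and reports the fraction of
questions flagged significant, which should sit near the nominal 0.05
level.  Writes results/calibration/calibration.json.
"""

import json
import math
from pathlib import Path

from concordex.pipeline import RunConfig, run_pipeline

REPO = Path(__file__).resolve().parent.parent
DATA = REPO / "scratch" / "analysis_data"
ROOT = REPO / "results"
SEED = 2024


def main() -> None:
    result = run_pipeline(
        DATA / "null_corpus.csv",
        RunConfig(null_samples=1000, seed=SEED, project=False),
    )
    n = len(result.question_results)
    n_sig = sum(r.significant for r in result.question_results)
    frac = n_sig / n
    se = math.sqrt(0.05 * 0.95 / n)
    band = (0.05 - 3 * se, 0.05 + 3 * se)
    out = {
        "n_questions": n,
        "n_significant": n_sig,
        "rejection_rate": frac,
        "nominal_level": 0.05,
        "three_se_band": band,
        "calibrated": band[0] <= frac <= band[1],
    }
    outdir = ROOT / "calibration"
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "calibration.json").write_text(json.dumps(out, indent=1))
    print(f"rejection rate under the null: {frac:.4f} "
          f"(nominal 0.05, 3-SE band [{band[0]:.3f}, {band[1]:.3f}])")
    print(f"calibrated: {out['calibrated']}")


if __name__ == "__main__":
    main()
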