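"""Cross-validated estimation of UCLA Loneliness scores (regression) and
detection of high-loneliness participants (binary classification, cutoff =
mean + 1 SD) from speech features.

Evaluates the prosodic (P), acoustic (A), linguistic (L) and combined
(P+A+L) input sets under iterated 10-fold cross-validation with per-fold
top-16 acoustic pre-selection and sequential forward selection.  Writes
results/evaluation.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lonespeech.cli_io import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", default=str(ROOT / "scratch" / "cohort" / "features.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--iters", type=int, default=10)
    ap.add_argument("--out", default=str(ROOT / "results" / "evaluation.json"))
    args = ap.parse_args()

    table = pd.read_csv(args.features)
    config = RunConfig(seed=args.seed, cv_iterations=args.iters)
    report = run_pipeline(table, config)

    Path(args.out).parent.mkdir(exist_ok=True)
    Path(args.out).write_text(json.dumps(report, indent=2, default=float) + "\n")

    print(f"cutoff {report['cutoff']} -> {report['n_high']} high-loneliness "
          f"participants of {len(table)}")
    print("regression R^2 by input set:")
    for which, rep in report["regression"].items():
        m = rep["metrics"]["r2"]
        print(f"  {which:<7} {m['mean']:+.3f}  CI [{m['ci'][0]:+.3f}, {m['ci'][1]:+.3f}]")
    clf = report["classification"]["P+A+L"]["metrics"]
    print("classification (P+A+L): "
          + ", ".join(f"{k} {v['mean']:.3f}" for k, v in clf.items()))


if __name__ == "__main__":
    main()
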