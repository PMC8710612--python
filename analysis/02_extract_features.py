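"""Extract the 160-dimensional speech feature vector for every participant:
128 acoustic (F1, F2, 14 delta-MFCC variances x 8 questions), 16 prosodic
(pitch variation, pause duration x 8) and 16 linguistic (positive/negative
word counts on 4 questions, filler proportion on 8).

Reads the cohort produced by 01_simulate_cohort.py and writes
results/features.csv.
"""

import argparse
import time
from pathlib import Path

import pandas as pd

from lonespeech.cli_io import extract_from_manifest, read_manifest
from lonespeech.linguistic_features import SentimentLexicon, load_filler_set

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default=str(ROOT / "scratch" / "cohort"))
    ap.add_argument("--out", default=str(ROOT / "scratch" / "cohort" / "features.csv"))
    args = ap.parse_args()

    cohort = Path(args.cohort)
    t0 = time.time()
    table = extract_from_manifest(
        read_manifest(cohort / "manifest.csv"),
        pd.read_csv(cohort / "participants.csv"),
        SentimentLexicon.from_tsv(cohort / "lexicon.tsv"),
        load_filler_set(cohort / "fillers.txt"),
        base_dir=cohort,
    )
    Path(args.out).parent.mkdir(exist_ok=True)
    table.to_csv(args.out, index=False)
    n_feat = table.shape[1] - 4
    print(f"extracted {len(table)} participants x {n_feat} features "
          f"in {time.time() - t0:.0f}s -> {args.out}")
    assert n_feat == 160, "feature schema violated"


if __name__ == "__main__":
    main()
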