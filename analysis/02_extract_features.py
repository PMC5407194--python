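#!/usr/bin/env python
"""Extract the 15 variables x 5 sections from every duet of the cohort.

Reads scratch/cohort/*.mid with their *_beats.csv sidecars (run
01_simulate_cohort.py first) and writes one row per participant to
results/features.csv.  Deviation statistics are in seconds, tempi in BPM,
LP/TC_o/RS/AI in proportions, DN in notes per beat.
"""

import sys
from pathlib import Path

from improvsync.cli import run_extract

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data_dir = ROOT / "scratch" / "cohort"
    if not data_dir.exists():
        sys.exit("no cohort data found — run analysis/01_simulate_cohort.py first")
    out_csv = ROOT / "results" / "features.csv"
    features = run_extract(data_dir, out_csv)
    print(f"extracted {len(features)} participants x {len(features.columns) - 1} features")
    md = features[["MD_m_B1", "MD_m_B2"]].describe().loc[["mean", "std"]]
    print("MD_m across the B bisection (seconds):")
    print(md.to_string(float_format=lambda v: f"{v:.4f}"))
    print(f"feature table: {out_csv}")


if __name__ == "__main__":
    main()
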