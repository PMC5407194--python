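#!/usr/bin/env python
"""Correlates of the improvement variable MD_m_B1 − MD_m_B2.

Positive values mean deviations shrink over the freer B section — improving
interpersonal synchronization.  The variable is screened against attachment
(ECR-R avoidance and anxiety), musical sophistication, beat perception, and
the patient-only clinical covariates, per group; avoidance + anxiety are then
entered together in a two-predictor regression among patients.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from improvsync import cohort_stats as cs

ROOT = Path(__file__).resolve().parents[1]

COVARIATES = [
    "avoidance", "anxiety",
    "gold_msi_general", "gold_msi_active_engagement", "gold_msi_perceptual_abilities",
    "gold_msi_musical_training", "gold_msi_singing_abilities", "gold_msi_emotions",
    "beat_perception", "did_severity", "medication_count",
]


def main() -> None:
    try:
        cohort = pd.read_csv(ROOT / "results" / "cohort.csv")
        features = pd.read_csv(ROOT / "results" / "features.csv")
    except FileNotFoundError:
        sys.exit("run analysis/01_simulate_cohort.py and 02_extract_features.py first")
    table = cohort.merge(features, on="participant_id")

    improvement = cs.improvement_variable(table)
    report = cs.covariate_screen(table, improvement, COVARIATES)

    corr = pd.DataFrame(report["correlations"])
    sig = corr[corr["p"] < 0.05]
    print("significant correlations with MD_m_B1 - MD_m_B2 (uncorrected p < 0.05):")
    print(sig.to_string(index=False) if not sig.empty else "  none")

    reg = report.get("attachment_regression")
    if reg:
        print(
            f"\navoidance + anxiety explain {100 * reg['r_squared']:.0f}% of the variance "
            f"in the improvement variable among patients "
            f"[F({reg['df_model']}, {reg['df_resid']}) = {reg['f']:.2f}, p = {reg['p']:.4f}]"
        )
    welch = report["group_tests"].get("welch")
    if welch:
        print(
            f"group difference in improvement (Welch): t({welch['df']:.2f}) = "
            f"{welch['t']:.2f}, p = {welch['p']:.4f}"
        )

    corr.to_csv(ROOT / "results" / "attachment_correlates.csv", index=False)
    (ROOT / "results" / "attachment_report.json").write_text(json.dumps(report, indent=2))
    print(f"\ntables: {ROOT / 'results'}/attachment_correlates.csv, attachment_report.json")


if __name__ == "__main__":
    main()
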