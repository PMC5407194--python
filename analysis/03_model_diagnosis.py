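#!/usr/bin/env python
"""Diagnosis models: screening, three logistic regressions, LOOCV, baselines.

Reproduces the statistical stage on the synthetic cohort: a per-variable
Welch screen, then three binary regressions — (A) MD_m_B1 + MD_m_B2, the
metrical-deviation model; (B) LP_B1 alone; (C) LP_B1 + MDB_sd_B1, the
lag-seeded stepwise follow-up — each with deviances, AIC, Nagelkerke R² and
Hosmer–Lemeshow calibration, leave-one-out cross-validation at a 0.5
probability cut, and exact binomial guessing baselines.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from improvsync import cohort_stats as cs

ROOT = Path(__file__).resolve().parents[1]

MODELS = {
    "A": ["MD_m_B1", "MD_m_B2"],
    "B": ["LP_B1"],
    "C": ["LP_B1", "MDB_sd_B1"],
}


def main() -> None:
    try:
        cohort = pd.read_csv(ROOT / "results" / "cohort.csv")
        features = pd.read_csv(ROOT / "results" / "features.csv")
    except FileNotFoundError:
        sys.exit("run analysis/01_simulate_cohort.py and 02_extract_features.py first")
    table = cohort.merge(features, on="participant_id")

    feature_cols = [c for c in features.columns if c != "participant_id"]
    screen = cs.screen_variables(table, feature_cols)
    print("top of the single-variable Welch screen (raw p, uncorrected):")
    print(screen.head(5)[["variable", "t", "df", "p"]].to_string(index=False))
    print()

    fits = {label: cs.fit_logistic(table, terms) for label, terms in MODELS.items()}
    print(cs.regression_table_text(fits))

    report = {"screen": screen.to_dict(orient="records"), "models": {}}
    for label, terms in MODELS.items():
        fit = fits[label]
        cv = cs.loocv(table, terms)
        report["models"][label] = {
            "terms": terms,
            "coef": fit.coef, "se": fit.se, "z": fit.z, "p": fit.p,
            "null_deviance": fit.null_deviance, "deviance": fit.deviance,
            "aic": fit.aic, "nagelkerke_r2": fit.nagelkerke_r2,
            "hosmer_lemeshow": {"chi2": fit.hl_chi2, "df": fit.hl_df, "p": fit.hl_p},
            "loocv_error": cv.error, "loocv_correct": cv.n_correct,
        }
        print(f"model {label}: LOOCV error {cv.error:.2f} ({cv.n_correct}/{cv.n} correct)")

    cv_a = report["models"]["A"]
    n = len(table)
    k = cv_a["loocv_correct"]
    prevalence = float((table["group"] == 1).mean())
    report["baseline"] = {
        "p_more_than_k_at_half": cs.binomial_baseline(n, k - 1, 0.5),
        "p_more_than_k_at_prevalence": cs.binomial_baseline(n, k - 1, prevalence),
    }
    print(
        f"\nguessing baseline: P(X > {k - 1} | n={n}, p=0.5) = "
        f"{report['baseline']['p_more_than_k_at_half']:.3f}; "
        f"at p={prevalence:.2f}: {report['baseline']['p_more_than_k_at_prevalence']:.3f}"
    )
    aics = {label: fits[label].aic for label in MODELS}
    best = min(aics, key=aics.get)
    print(f"AIC favours model {best}: " + ", ".join(f"{m}={a:.2f}" for m, a in aics.items()))

    out = ROOT / "results" / "model_report.json"
    out.write_text(json.dumps(report, indent=2))
    (ROOT / "results" / "model_summary.txt").write_text(cs.regression_table_text(fits))
    print(f"\nfull report: {out}")


if __name__ == "__main__":
    main()
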