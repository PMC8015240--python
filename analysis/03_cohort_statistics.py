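"""Cohort-level statistics on patient CIs and clinical covariates.

Normality (Shapiro-Wilk per group), one-way ANOVA on mean CI by group with
Tukey HSD post hoc gated on a significant ANOVA, Kruskal-Wallis on PSA and
prostate size, chi-square on smoking, Welch t on CI by smoking status and
Gleason category, and the CI-vs-covariate Pearson correlation matrix with
Holm-adjusted p-values.

Reads results/patient_ci.csv + results/patients.csv; writes
results/stats_report.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from nsdt.pipeline import read_patients
from nsdt.stats import run_cohort_stats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    patient_ci = pd.read_csv(args.out / "patient_ci.csv")
    patients = read_patients(args.out / "patients.csv")
    report = run_cohort_stats(patient_ci, patients)
    report.to_csv(args.out / "stats_report.csv", index=False)

    anova = report[report["target"] == "mean_ci~group"].iloc[0]
    print(f"one-way ANOVA on mean CI by group: F={anova['statistic']:.2f}, "
          f"p={anova['p_value']:.4f}")
    for _, row in report[report["test"] == "tukey_hsd"].iterrows():
        print(f"  Tukey {row['target']}: p={row['p_value']:.3f}")
    kw = report[report["target"] == "psa~group"].iloc[0]
    print(f"Kruskal-Wallis on PSA by group: H={kw['statistic']:.1f}, "
          f"p={kw['p_value']:.2g}")
    ci_corrs = report[(report["test"] == "pearson_r")
                      & report["target"].str.startswith("mean_ci")]
    print("CI vs clinical covariates (Pearson r, Holm-adjusted p):")
    for _, row in ci_corrs.iterrows():
        print(f"  {row['target']}: r={row['statistic']:+.2f}, "
              f"p_adj={row['p_value']:.2f}")
    print(f"wrote {args.out / 'stats_report.csv'}")


if __name__ == "__main__":
    main()
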