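"""Rule-based classification: CI sign, PSA threshold, and their AND combination.

Evaluates the three fixed-threshold classifiers against the pathology group
label (positive class = cancer; benign and negative screen are cancer-free):
confusion matrices, sensitivity/specificity/accuracy/balanced accuracy, the
no-information rate with a one-sided exact binomial accuracy test, and
McNemar's test of each classifier against pathology.

Reads results/patient_ci.csv + results/patients.csv; writes
results/classification_report.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from nsdt.diagnostics import evaluate_models
from nsdt.pipeline import read_patients


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    patient_ci = pd.read_csv(args.out / "patient_ci.csv")
    patients = read_patients(args.out / "patients.csv")
    rep = evaluate_models(patient_ci, patients)
    rep.to_csv(args.out / "classification_report.csv", index=False)

    for _, row in rep.iterrows():
        print(f"{row['model']:>13}: sens {row['sensitivity']:.0%}  "
              f"spec {row['specificity']:.0%}  acc {row['accuracy']:.0%}  "
              f"bal acc {row['balanced_accuracy']:.0%}  "
              f"(NIR {row['nir']:.0%}, acc>NIR p={row['acc_vs_nir_p']:.3f}, "
              f"McNemar p={row['mcnemar_p']:.3g})")
    comb = rep.set_index("model").loc["combined_rule"]
    ci = rep.set_index("model").loc["ci_rule"]
    print(f"combined rule trades sensitivity "
          f"({ci['sensitivity']:.0%} -> {comb['sensitivity']:.0%}) for "
          f"specificity ({ci['specificity']:.0%} -> {comb['specificity']:.0%})")
    print(f"wrote {args.out / 'classification_report.csv'}")


if __name__ == "__main__":
    main()
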