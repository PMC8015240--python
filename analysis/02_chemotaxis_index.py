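"""Aggregate plate counts to one chemotaxis index per patient.

Applies the CI statistic to every plate, caps oversampled patients at six
technical replicates by random subsampling, excludes degenerate plates, and
averages to one CI (with SEM) per patient.

Reads results/assays.csv; writes results/patient_ci.csv and
results/exclusions.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nsdt.pipeline import compute_patient_ci_table, read_assays


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    assays = read_assays(args.out / "assays.csv")
    table, exclusions = compute_patient_ci_table(
        assays, subsample_k=6, rng=np.random.default_rng(args.seed))
    table.to_csv(args.out / "patient_ci.csv", index=False)
    pd.DataFrame(exclusions, columns=["patient_id", "dilution",
                                      "replicate_index", "reason"]
                 ).to_csv(args.out / "exclusions.csv", index=False)

    print(f"{len(table)} patient CIs from {len(assays)} plates "
          f"({len(exclusions)} plates excluded)")
    means = table.groupby("group")["mean_ci"].agg(["mean", "sem", "count"])
    print("group-level mean CI (of patient means):")
    print(means.round(3).to_string())
    sign = (np.sign(table["mean_ci"]) > 0).groupby(table["group"]).mean()
    print(f"fraction of patients with attractive urine (CI>0):\n"
          f"{sign.round(2).to_string()}")
    print(f"wrote {args.out / 'patient_ci.csv'}")


if __name__ == "__main__":
    main()
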