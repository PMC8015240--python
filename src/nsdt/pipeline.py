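"""End-to-end pipeline: simulate -> CI -> cohort stats -> classification.

CSV schemas (comma-separated, UTF-8, header row, dot decimals, missing
values as empty fields):

* ``assays.csv``      — patient_id, group, dilution, t1, t2, c1, c2, center,
  block, replicate_index
* ``patients.csv``    — patient_id, group, psa_ng_ml, age_years, bmi,
  prostate_cm3, smoker, gleason_cat
* ``patient_ci.csv``  — patient_id, group, dilution, mean_ci, sem_ci, n_used,
  qc_pass
* ``stats_report.csv``, ``classification_report.csv``, ``dilution_screen.csv``
  as produced by the stats and diagnostics stages.

Every stochastic step draws from a stream derived from the single run seed,
so identical config+seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemotaxis import (AssayReplicate, QuadrantCounts, UndefinedCIError,
                         aggregate_patient, subsample_replicates)
from .diagnostics import evaluate_models, select_optimal_dilution
from .simulate import (GROUPS, SimulationParams, SyntheticCohort,
                       simulate_cohort, simulate_dilution_screen)
from .stats import run_cohort_stats

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SchemaError",
    "cohort_to_frames",
    "read_assays",
    "read_patients",
    "compute_patient_ci_table",
    "cmd_simulate",
    "cmd_analyze",
    "cmd_dilution_screen",
]

ASSAY_COLUMNS = ["patient_id", "group", "dilution", "t1", "t2", "c1", "c2",
                 "center", "block", "replicate_index"]
PATIENT_COLUMNS = ["patient_id", "group", "psa_ng_ml", "age_years", "bmi",
                   "prostate_cm3", "smoker", "gleason_cat"]


class SchemaError(ValueError):
    """An input CSV does not conform to the expected schema."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    out_dir: Path = Path("results")
    sim: SimulationParams = field(default_factory=SimulationParams)
    subsample_k: int = 6
    ci_cutoff: float = 0.0
    psa_cutoff: float = 4.0
    qc_min_mean_ci: float = 0.5
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "replicate_probs" in sim_raw:
            sim_raw["replicate_probs"] = {int(k): float(v)
                                          for k, v in sim_raw["replicate_probs"].items()}
        for key in ("psa_params",):
            if key in sim_raw:
                sim_raw[key] = {g: tuple(v) for g, v in sim_raw[key].items()}
        cfg = cls(sim=SimulationParams(**sim_raw), **{
            k: (Path(v) if k == "out_dir" else v) for k, v in raw.items()
        })
        if seed is not None:
            cfg.seed = seed
        return cfg


# ---------------------------------------------------------------------------
# frame conversion and validated IO

def cohort_to_frames(cohort: SyntheticCohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into the assays/patients CSV schemas."""
    group_of = {p.patient_id: p.group for p in cohort.patients}
    assays = pd.DataFrame([{
        "patient_id": a.patient_id, "group": group_of[a.patient_id],
        "dilution": a.dilution, "t1": a.counts.t1, "t2": a.counts.t2,
        "c1": a.counts.c1, "c2": a.counts.c2, "center": a.counts.center,
        "block": a.block, "replicate_index": a.replicate_index,
    } for a in cohort.assays], columns=ASSAY_COLUMNS)
    patients = pd.DataFrame([{
        "patient_id": p.patient_id, "group": p.group, "psa_ng_ml": p.psa_ng_ml,
        "age_years": p.age_years, "bmi": p.bmi, "prostate_cm3": p.prostate_cm3,
        "smoker": p.smoker, "gleason_cat": p.gleason_cat or "",
    } for p in cohort.patients], columns=PATIENT_COLUMNS)
    return assays, patients


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def read_assays(path: str | Path) -> pd.DataFrame:
    """Read and validate an assays table; itemizes offending rows."""
    df = pd.read_csv(path)
    _require_columns(df, ASSAY_COLUMNS, "assays")
    bad: list[str] = []
    for col in ("t1", "t2", "c1", "c2", "center"):
        vals = pd.to_numeric(df[col], errors="coerce")
        mask = vals.isna() | (vals < 0) | (vals != vals.round())
        if mask.any():
            bad.extend(f"row {i}: {col}={df[col].iloc[i]!r}"
                       for i in df.index[mask][:10])
    unknown = ~df["group"].isin(GROUPS)
    if unknown.any():
        bad.extend(f"row {i}: group={df['group'].iloc[i]!r}"
                   for i in df.index[unknown][:10])
    if bad:
        raise SchemaError("assays schema violations:\n  " + "\n  ".join(bad))
    return df


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PATIENT_COLUMNS, "patients")
    bad: list[str] = []
    unknown = ~df["group"].isin(GROUPS)
    if unknown.any():
        bad.extend(f"row {i}: group={df['group'].iloc[i]!r}"
                   for i in df.index[unknown][:10])
    psa = pd.to_numeric(df["psa_ng_ml"], errors="coerce")
    neg = df["psa_ng_ml"].notna() & (psa <= 0)
    if neg.any():
        bad.extend(f"row {i}: psa_ng_ml={df['psa_ng_ml'].iloc[i]!r}"
                   for i in df.index[neg][:10])
    if df["patient_id"].duplicated().any():
        bad.append("duplicate patient_id values")
    if bad:
        raise SchemaError("patients schema violations:\n  " + "\n  ".join(bad))
    return df


# ---------------------------------------------------------------------------
# pipeline stages

def compute_patient_ci_table(
    assays: pd.DataFrame,
    subsample_k: int = 6,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-patient CI aggregation with replicate subsampling.

    Oversampled patients (more than ``subsample_k`` technical replicates) are
    capped by uniform random subsampling; degenerate plates are excluded.
    Returns the patient_ci table and an exclusion log (one entry per dropped
    or degenerate replicate) so every input row is accounted for.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows, exclusions = [], []
    for (pid, dil), sub in assays.groupby(["patient_id", "dilution"], sort=True):
        reps = [AssayReplicate(
            patient_id=str(pid), dilution=str(dil),
            counts=QuadrantCounts(t1=int(r.t1), t2=int(r.t2), c1=int(r.c1),
                                  c2=int(r.c2), center=int(r.center)),
            block=str(r.block), replicate_index=int(r.replicate_index),
        ) for r in sub.itertuples()]
        kept = subsample_replicates(reps, k=subsample_k, rng=rng)
        kept_idx = {id(r) for r in kept}
        for r in reps:
            if id(r) not in kept_idx:
                exclusions.append({"patient_id": pid, "dilution": dil,
                                   "replicate_index": r.replicate_index,
                                   "reason": "subsampled_out"})
        try:
            agg = aggregate_patient(kept)
        except UndefinedCIError:
            for r in kept:
                exclusions.append({"patient_id": pid, "dilution": dil,
                                   "replicate_index": r.replicate_index,
                                   "reason": "degenerate_plate"})
            logger.warning("patient %s @ %s: all plates degenerate, skipped",
                           pid, dil)
            continue
        for r in kept:
            if r.ci is None:
                exclusions.append({"patient_id": pid, "dilution": dil,
                                   "replicate_index": r.replicate_index,
                                   "reason": "degenerate_plate"})
        rows.append({
            "patient_id": pid, "group": sub["group"].iloc[0], "dilution": dil,
            "mean_ci": agg.mean_ci, "sem_ci": agg.sem_ci, "n_used": agg.n_used,
            "qc_pass": True,
        })
    return pd.DataFrame(rows), exclusions


def _write_manifest(out_dir: Path, cfg: RunConfig, inputs: dict[str, Path]) -> None:
    def sha(p: Path) -> str:
        return hashlib.sha256(p.read_bytes()).hexdigest()[:16]

    manifest = {
        "nsdt_version": __version__,
        "seed": cfg.seed,
        "params": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "input_hashes": {name: sha(p) for name, p in inputs.items() if p.exists()},
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")


def cmd_simulate(cfg: RunConfig) -> tuple[Path, Path]:
    """Generate a synthetic cohort and write assays.csv + patients.csv."""
    if sum(cfg.sim.n_per_group.values()) == 0:
        raise ValueError("n_per_group: at least one group must be non-empty")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg.sim, seed=cfg.seed)
    assays, patients = cohort_to_frames(cohort)
    a_path, p_path = out / "assays.csv", out / "patients.csv"
    assays.to_csv(a_path, index=False)
    patients.to_csv(p_path, index=False)
    _write_manifest(out, cfg, {"assays": a_path, "patients": p_path})
    logger.info("wrote %d patients, %d assays", len(patients), len(assays))
    return a_path, p_path


def cmd_analyze(
    cfg: RunConfig,
    assays_path: str | Path,
    patients_path: str | Path,
) -> dict[str, pd.DataFrame]:
    """Full analysis: CI aggregation, cohort stats, rule classification.

    Writes patient_ci.csv, stats_report.csv, classification_report.csv and
    exclusions.csv under the configured output directory and returns the
    tables.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assays = read_assays(assays_path)
    patients = read_patients(patients_path)
    rng = np.random.default_rng(cfg.seed)
    patient_ci, exclusions = compute_patient_ci_table(
        assays, subsample_k=cfg.subsample_k, rng=rng)
    patient_ci.to_csv(out / "patient_ci.csv", index=False)
    pd.DataFrame(exclusions, columns=["patient_id", "dilution",
                                      "replicate_index", "reason"]
                 ).to_csv(out / "exclusions.csv", index=False)
    results: dict[str, pd.DataFrame] = {"patient_ci": patient_ci}
    n_groups = patients["group"].nunique()
    if n_groups >= 2:
        stats_report = run_cohort_stats(patient_ci, patients, alpha=cfg.alpha)
        stats_report.to_csv(out / "stats_report.csv", index=False)
        results["stats_report"] = stats_report
        class_report = evaluate_models(patient_ci, patients,
                                       ci_cutoff=cfg.ci_cutoff,
                                       psa_cutoff=cfg.psa_cutoff)
        class_report.to_csv(out / "classification_report.csv", index=False)
        results["classification_report"] = class_report
    else:
        logger.warning("single-group cohort: stats and classification skipped")
    _write_manifest(out, cfg, {"assays": Path(assays_path),
                               "patients": Path(patients_path)})
    return results


def cmd_dilution_screen(
    cfg: RunConfig,
    assays_path: str | Path | None = None,
    patients_path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-dilution discrimination criteria and the selected dilution.

    Without input paths, simulates the preliminary screen (4 patients per
    group at five serial dilutions).  With inputs, requires >= 2 dilutions;
    patients not assayed at every dilution are dropped with a warning so all
    dilutions are compared on the common panel.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if assays_path is None:
        cohort = simulate_dilution_screen(cfg.sim, seed=cfg.seed)
        assays, patients = cohort_to_frames(cohort)
    else:
        assays = read_assays(assays_path)
        patients = read_patients(patients_path)
    if assays["dilution"].nunique() < 2:
        raise ValueError("dilution screen needs assays at >= 2 dilutions")
    rng = np.random.default_rng(cfg.seed)
    patient_ci, _ = compute_patient_ci_table(assays, subsample_k=cfg.subsample_k,
                                             rng=rng)
    counts = patient_ci.groupby("patient_id")["dilution"].nunique()
    n_dil = patient_ci["dilution"].nunique()
    common = set(counts[counts == n_dil].index)
    dropped = set(counts.index) - common
    if dropped:
        logger.warning("restricting to common panel; dropped %s", sorted(dropped))
        patient_ci = patient_ci[patient_ci["patient_id"].isin(common)]
    per_dilution = {
        dil: list(zip(sub["mean_ci"], sub["group"]))
        for dil, sub in patient_ci.groupby("dilution", sort=False)
    }
    best, table = select_optimal_dilution(per_dilution, ci_cutoff=cfg.ci_cutoff)
    table.to_csv(out / "dilution_screen.csv", index=False)
    logger.info("selected dilution: %s", best)
    return table
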