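"""Rule-based diagnostic classifiers and their evaluation.

Three fixed-threshold classifiers are compared against pathology-confirmed
disease status (positive class = prostate cancer; benign and negative-screen
patients are both cancer-free):

* ``ci_rule``       — call cancer iff the patient's mean chemotaxis index > 0
* ``psa_rule``      — call cancer iff PSA >= 4 ng/ml (the conventional cutoff)
* ``combined_rule`` — AND combination: both conditions required

Evaluation produces confusion-matrix metrics (sensitivity, specificity,
accuracy, balanced accuracy), a one-sided exact binomial comparison of
accuracy against the no-information rate (NIR, the majority-class
prevalence), and McNemar's test of each classifier against the pathology
reference.  A mean CI of exactly 0 is assigned to the cancer-free class
(conservative toward fewer false positives; configurable via ``ci_cutoff``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

logger = logging.getLogger(__name__)

__all__ = [
    "CANCER",
    "CANCER_FREE",
    "RuleClassifier",
    "ConfusionMatrix",
    "ClassificationReport",
    "classify",
    "confusion",
    "report",
    "nir_test",
    "mcnemar",
    "select_optimal_dilution",
    "evaluate_models",
]

CANCER = "cancer"
CANCER_FREE = "cancer_free"


@dataclass(frozen=True)
class RuleClassifier:
    """A fixed-threshold rule; ``combined_rule`` ANDs the CI and PSA conditions."""

    name: str  # 'ci_rule' | 'psa_rule' | 'combined_rule'
    ci_cutoff: float = 0.0
    psa_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.name not in ("ci_rule", "psa_rule", "combined_rule"):
            raise ValueError(f"unknown rule {self.name!r}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; positive class is pathology-confirmed prostate cancer."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def _round_half_up_pct(x: float) -> int:
    """Round a proportion to an integer percent, halves away from zero."""
    return int(math.floor(100.0 * x + 0.5))


@dataclass
class ClassificationReport:
    """Metrics of one classifier; raw proportions plus integer-percent display."""

    cm: ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    nir: float
    acc_vs_nir_p: float
    mcnemar_p: float | None = None

    @property
    def display(self) -> dict[str, int]:
        """Integer-percent (half-up) metrics for table display."""
        out = {}
        for k in ("sensitivity", "specificity", "accuracy", "balanced_accuracy",
                  "nir"):
            v = getattr(self, k)
            if not math.isnan(v):
                out[k] = _round_half_up_pct(v)
        return out


def classify(
    mean_ci: float | None,
    psa: float | None,
    rule: RuleClassifier,
) -> str:
    """Apply one rule to one patient; returns CANCER or CANCER_FREE.

    Raises ValueError when an input the rule requires is missing — callers
    exclude such patients from that model's evaluation.
    """
    if rule.name in ("ci_rule", "combined_rule") and (
        mean_ci is None or (isinstance(mean_ci, float) and math.isnan(mean_ci))
    ):
        raise ValueError(f"{rule.name} requires mean_ci")
    if rule.name in ("psa_rule", "combined_rule") and (
        psa is None or (isinstance(psa, float) and math.isnan(psa))
    ):
        raise ValueError(f"{rule.name} requires psa")
    ci_call = mean_ci is not None and mean_ci > rule.ci_cutoff
    psa_call = psa is not None and psa >= rule.psa_cutoff
    if rule.name == "ci_rule":
        return CANCER if ci_call else CANCER_FREE
    if rule.name == "psa_rule":
        return CANCER if psa_call else CANCER_FREE
    return CANCER if (ci_call and psa_call) else CANCER_FREE


_TRUTH_MAP = {"cancer": CANCER, "benign": CANCER_FREE,
              "negative_screen": CANCER_FREE, CANCER_FREE: CANCER_FREE}


def confusion(predictions, truth) -> ConfusionMatrix:
    """Tally a confusion matrix from aligned label vectors.

    Truth labels may be cohort groups (benign and negative_screen both map to
    cancer-free) or already-binary labels.
    """
    preds = list(predictions)
    trues = list(truth)
    if len(preds) != len(trues):
        raise ValueError("predictions and truth must be aligned")
    tp = fn = fp = tn = 0
    for p, t in zip(preds, trues):
        if p not in (CANCER, CANCER_FREE):
            raise ValueError(f"unknown predicted label {p!r}")
        if t not in _TRUTH_MAP:
            raise ValueError(f"unknown truth label {t!r}")
        t = _TRUTH_MAP[t]
        if t == CANCER:
            tp += p == CANCER
            fn += p == CANCER_FREE
        else:
            fp += p == CANCER
            tn += p == CANCER_FREE
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def report(cm: ConfusionMatrix, mcnemar_p: float | None = None) -> ClassificationReport:
    """Diagnostic metrics of a confusion matrix.

    Sensitivity is NaN (flagged) when there are no true positives in the
    cohort; balanced accuracy is the unweighted mean of sensitivity and
    specificity.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if cm.n_positive == 0:
        logger.warning("no positive cases: sensitivity undefined")
        sens = float("nan")
    else:
        sens = cm.tp / cm.n_positive
    spec = cm.tn / cm.n_negative if cm.n_negative > 0 else float("nan")
    acc = (cm.tp + cm.tn) / cm.total
    bal = (sens + spec) / 2.0
    nir, p = nir_test(cm)
    return ClassificationReport(
        cm=cm, sensitivity=sens, specificity=spec, accuracy=acc,
        balanced_accuracy=bal, nir=nir, acc_vs_nir_p=p, mcnemar_p=mcnemar_p,
    )


def nir_test(cm: ConfusionMatrix) -> tuple[float, float]:
    """No-information rate and one-sided exact binomial test of accuracy > NIR.

    NIR is the majority-class prevalence — the accuracy of always predicting
    the larger class.  The test asks whether the observed number of correct
    calls exceeds what a majority-class predictor achieves, with
    n = cohort size.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    nir = max(cm.n_positive, cm.n_negative) / cm.total
    correct = cm.tp + cm.tn
    p = binomtest(correct, cm.total, nir, alternative="greater").pvalue
    return float(nir), float(p)


def mcnemar(predictions, reference, exact: bool = False) -> tuple[float, float]:
    """McNemar's paired test of two label vectors on the same patients.

    Default: chi-square with continuity correction on the discordant counts
    b, c — statistic (|b-c|-1)^2/(b+c) on 1 df.  ``exact=True`` switches to
    the exact binomial form (preferred when b+c is small).  With no
    discordant pairs the test is degenerate: returns (0.0, 1.0), flagged.
    """
    preds = list(predictions)
    refs = list(reference)
    if len(preds) != len(refs):
        raise ValueError("label vectors must be aligned")
    labels = (CANCER, CANCER_FREE)
    b = sum(1 for p, r in zip(preds, refs) if p == labels[0] and r == labels[1])
    c = sum(1 for p, r in zip(preds, refs) if p == labels[1] and r == labels[0])
    both = sum(1 for p, r in zip(preds, refs) if p == r == labels[0])
    neither = sum(1 for p, r in zip(preds, refs) if p == r == labels[1])
    if b + c == 0:
        logger.warning("McNemar degenerate: no discordant pairs; p = 1")
        return 0.0, 1.0
    table = [[both, b], [c, neither]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.statistic), float(res.pvalue)


def select_optimal_dilution(
    per_dilution: dict[str, list[tuple[float, str]]],
    ci_cutoff: float = 0.0,
) -> tuple[str, pd.DataFrame]:
    """Pick the urine dilution that best separates cancer from controls.

    ``per_dilution`` maps a dilution label to (mean CI, truth group) pairs for
    the screened panel.  For each dilution two criteria are computed: (a) the
    accuracy of the CI sign rule and (b) the mean CI difference (cancer minus
    controls).  The dilution with the highest accuracy wins; ties break on the
    larger mean difference, then toward the least-dilute option (stable order
    of the input mapping).  Returns the winner and the per-dilution table.
    """
    if len(per_dilution) < 2:
        raise ValueError("need >= 2 dilutions to screen")
    rows = []
    for dil, pairs in per_dilution.items():
        truths = [t for _, t in pairs]
        mapped = [_TRUTH_MAP.get(t) for t in truths]
        if CANCER not in mapped or CANCER_FREE not in mapped:
            raise ValueError(f"dilution {dil!r} needs >= 1 cancer and >= 1 control")
        preds = [CANCER if ci > ci_cutoff else CANCER_FREE for ci, _ in pairs]
        cm = confusion(preds, truths)
        acc = (cm.tp + cm.tn) / cm.total
        can = [ci for ci, t in pairs if _TRUTH_MAP[t] == CANCER]
        ctl = [ci for ci, t in pairs if _TRUTH_MAP[t] == CANCER_FREE]
        rows.append({"dilution": dil, "sign_accuracy": acc,
                     "mean_ci_difference": float(np.mean(can) - np.mean(ctl))})
    table = pd.DataFrame(rows)
    order = np.lexsort((
        np.arange(len(table))[::-1],          # earlier (least dilute) wins ties
        table["mean_ci_difference"].to_numpy(),
        table["sign_accuracy"].to_numpy(),
    ))
    best = table.iloc[order[-1]]["dilution"]
    table["selected"] = table["dilution"] == best
    return str(best), table


def evaluate_models(
    patient_ci: pd.DataFrame,
    patients: pd.DataFrame,
    ci_cutoff: float = 0.0,
    psa_cutoff: float = 4.0,
) -> pd.DataFrame:
    """Evaluate the three rule classifiers on a cohort table.

    Patients missing an input a model requires are excluded from that model
    only (logged); each row reports the model's effective cohort size.
    """
    df = patient_ci.merge(patients, on=["patient_id", "group"], how="inner")
    rules = [RuleClassifier("ci_rule", ci_cutoff, psa_cutoff),
             RuleClassifier("psa_rule", ci_cutoff, psa_cutoff),
             RuleClassifier("combined_rule", ci_cutoff, psa_cutoff)]
    rows = []
    for rule in rules:
        preds, truths = [], []
        n_excluded = 0
        for _, row in df.iterrows():
            try:
                pred = classify(row.get("mean_ci"), row.get("psa_ng_ml"), rule)
            except ValueError:
                n_excluded += 1
                logger.info("patient %s excluded from %s (missing input)",
                            row["patient_id"], rule.name)
                continue
            preds.append(pred)
            truths.append(row["group"])
        if not preds or len(set(_TRUTH_MAP[t] for t in truths)) < 2:
            logger.warning("%s: degenerate cohort, skipped", rule.name)
            continue
        cm = confusion(preds, truths)
        ref = [_TRUTH_MAP[t] for t in truths]
        _, mcn_p = mcnemar(preds, ref)
        rep = report(cm, mcnemar_p=mcn_p)
        rows.append({
            "model": rule.name, "n": cm.total, "n_excluded": n_excluded,
            "tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
            "accuracy": rep.accuracy, "balanced_accuracy": rep.balanced_accuracy,
            "nir": rep.nir, "acc_vs_nir_p": rep.acc_vs_nir_p,
            "mcnemar_p": mcn_p,
        })
    return pd.DataFrame(rows)
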