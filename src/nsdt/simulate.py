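"""Synthetic cohort and plate-count generator.

Emulates a three-group prostate-screening cohort (negative screen / benign /
cancer) assayed by the quadrant chemotaxis test, so the whole downstream
pipeline is testable without patient data.

Generative model
----------------
Each patient carries a latent attraction ``a`` in [-1, 1]: the group mean
attraction is mapped to the logit of (1+a)/2, patient-level Gaussian noise is
added on that scale, and the result is mapped back.  Conditional on ``a``,
each plate is a single multinomial draw over (center, T1, T2, C1, C2): a worm
stays in the center circle with probability ``immobile_prob``; otherwise it
enters a test quadrant with probability (1+a)/2 (split evenly between T1 and
T2) or a control quadrant with the complementary probability (split evenly
between C1 and C2).  Worms migrate independently, so E[plate CI | a] = a
regardless of the immobile fraction — center worms are excluded from scoring.

PSA is drawn from group-specific log-normals truncated to the cohort's
inclusion window of [2.5, 20] ng/ml; the cancer and benign locations sit above
the negative-screen one.  Age, BMI, prostate size and smoking are generated
independently of attraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit
from scipy.stats import lognorm

from .chemotaxis import AssayReplicate, QuadrantCounts, UndefinedCIError, compute_ci

__all__ = [
    "GROUPS",
    "PSA_WINDOW",
    "SimulationParams",
    "PatientRecord",
    "SyntheticCohort",
    "simulate_assay",
    "simulate_cohort",
    "simulate_dilution_screen",
    "estimate_attraction",
]

GROUPS = ("negative_screen", "benign", "cancer")

#: Inclusion window for total PSA, ng/ml.
PSA_WINDOW = (2.5, 20.0)

#: Default study dilution at which patient samples are assayed.
DEFAULT_DILUTION = "1:100"

DILUTIONS = ("1:10", "1:50", "1:100", "1:500", "1:1000")


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for the synthetic cohort and plate model.

    Defaults encode the study conditions: cohort sizes 27/19/21, ~50 worms
    plated per assay with about a quarter remaining in the center circle
    (so 34-38 worms score per plate), 4-6 technical replicates per patient
    with 6 the most common, cancer urine mildly attractive and control urine
    mildly repulsive, and PSA truncated to the 2.5-20 ng/ml inclusion window
    with cancer/benign elevated over negative screens.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"negative_screen": 27, "benign": 19, "cancer": 21}
    )
    mean_attraction: dict[str, float] = field(
        default_factory=lambda: {"negative_screen": -0.05, "benign": -0.05,
                                 "cancer": 0.15}
    )
    #: Patient-level SD on the logit-of-(1+a)/2 scale (~half this on the
    #: attraction scale near a=0).
    between_patient_sd: float = 0.30
    n_worms_mean: float = 50.0
    n_worms_sd: float = 4.0
    immobile_prob: float = 0.25
    #: Probability of 4, 5 or 6 technical replicates per patient (mode 6).
    replicate_probs: dict[int, float] = field(
        default_factory=lambda: {4: 0.10, 5: 0.15, 6: 0.75}
    )
    #: Per-group (mu, sigma) of log(PSA) before truncation to PSA_WINDOW.
    psa_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "negative_screen": (np.log(2.9), 0.45),
            "benign": (np.log(4.5), 0.45),
            "cancer": (np.log(8.0), 0.45),
        }
    )
    #: (mean, sd) for age (years, clipped to the 45-75 inclusion window),
    #: BMI (kg/m2), prostate size by group (cm3); smoking prevalence.
    age_mean: float = 63.0
    age_sd: float = 7.0
    bmi_mean: float = 28.0
    bmi_sd: float = 4.0
    prostate_mean: dict[str, float] = field(
        default_factory=lambda: {"negative_screen": 40.0, "benign": 48.0,
                                 "cancer": 42.0}
    )
    prostate_sd: float = 15.0
    smoking_prevalence: float = 0.38
    #: P(low Gleason category | cancer); low = 3+3 or 3+4, high = >=4+3.
    gleason_low_prob: float = 13.0 / 21.0
    dilution: str = DEFAULT_DILUTION
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.n_per_group:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
        for g, a in self.mean_attraction.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in mean_attraction")
            if not -1.0 <= a <= 1.0:
                raise ValueError(f"mean_attraction[{g!r}]={a} outside [-1, 1]")
        if not 0.0 <= self.immobile_prob < 1.0:
            raise ValueError(f"immobile_prob must be in [0, 1), got {self.immobile_prob}")
        if not self.replicate_probs or min(self.replicate_probs) < 1:
            raise ValueError("replicates_per_patient must be >= 1")
        if abs(sum(self.replicate_probs.values()) - 1.0) > 1e-9:
            raise ValueError("replicate_probs must sum to 1")
        if self.between_patient_sd < 0:
            raise ValueError("between_patient_sd must be >= 0")


@dataclass
class PatientRecord:
    """Clinical covariates and pathology-confirmed group label."""

    patient_id: str
    group: str
    psa_ng_ml: float | None
    age_years: float
    bmi: float
    prostate_cm3: float | None
    smoker: bool
    gleason_cat: str | None = None  # 'low'/'high'; cancer only

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.gleason_cat is not None and self.group != "cancer":
            raise ValueError("gleason_cat present only for cancer patients")
        if self.psa_ng_ml is not None and self.psa_ng_ml <= 0:
            raise ValueError("psa must be > 0 when present")


@dataclass
class SyntheticCohort:
    """A generated cohort: patient records plus plate-level assay replicates."""

    patients: list[PatientRecord]
    assays: list[AssayReplicate]
    params: SimulationParams
    seed: int
    #: Latent per-patient attraction, kept for parameter-recovery checks.
    latent_attraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {p.patient_id for p in self.patients}
        for a in self.assays:
            if a.patient_id not in ids:
                raise ValueError(f"assay references unknown patient {a.patient_id!r}")


def simulate_assay(
    attraction: float,
    n_worms: int,
    immobile_prob: float,
    rng: np.random.Generator,
) -> QuadrantCounts:
    """Simulate one plate: multinomial endpoint counts for ``n_worms`` worms.

    Each worm independently stays in the center with probability
    ``immobile_prob``; otherwise it ends in a test quadrant with probability
    (1+attraction)/2 (uniform over T1/T2) or a control quadrant (uniform over
    C1/C2).  Counts sum to ``n_worms``.
    """
    if not -1.0 <= attraction <= 1.0:
        raise ValueError(f"attraction {attraction} outside [-1, 1]")
    if n_worms <= 0:
        raise UndefinedCIError("degenerate assay: n_worms must be positive")
    if not 0.0 <= immobile_prob < 1.0:
        raise ValueError(f"immobile_prob {immobile_prob} outside [0, 1)")
    p_test = (1.0 - immobile_prob) * (1.0 + attraction) / 2.0
    p_ctrl = (1.0 - immobile_prob) * (1.0 - attraction) / 2.0
    probs = [immobile_prob, p_test / 2, p_test / 2, p_ctrl / 2, p_ctrl / 2]
    center, t1, t2, c1, c2 = rng.multinomial(n_worms, probs)
    return QuadrantCounts(t1=int(t1), t2=int(t2), c1=int(c1), c2=int(c2),
                          center=int(center))


def _draw_truncated_lognormal(
    mu: float, sigma: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    """Inverse-CDF draw from a log-normal truncated to [lo, hi]."""
    dist = lognorm(s=sigma, scale=np.exp(mu))
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi))
    return float(np.clip(dist.ppf(u), lo, hi))


def _patient_attraction(
    group_mean: float, sd_logit: float, rng: np.random.Generator
) -> float:
    l0 = logit((1.0 + group_mean) / 2.0)
    return float(2.0 * expit(l0 + rng.normal(0.0, sd_logit)) - 1.0)


def simulate_cohort(params: SimulationParams, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort, reproducible given the seed.

    Per patient: a latent attraction (group mean plus logit-scale noise), a
    replicate count in the configured range, one multinomial plate per
    replicate, and a clinical record with truncated log-normal PSA and
    independent covariates.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    patients: list[PatientRecord] = []
    assays: list[AssayReplicate] = []
    latent: dict[str, float] = {}
    rep_ks = sorted(params.replicate_probs)
    rep_ps = [params.replicate_probs[k] for k in rep_ks]
    prefix = {"negative_screen": "N", "benign": "B", "cancer": "C"}
    for group in GROUPS:
        n = params.n_per_group.get(group, 0)
        mu_a = params.mean_attraction[group]
        psa_mu, psa_sigma = params.psa_params[group]
        for i in range(n):
            pid = f"{prefix[group]}{i + 1:02d}"
            a = _patient_attraction(mu_a, params.between_patient_sd, rng)
            latent[pid] = a
            n_reps = int(rng.choice(rep_ks, p=rep_ps))
            for r in range(n_reps):
                n_worms = max(1, int(round(rng.normal(params.n_worms_mean,
                                                      params.n_worms_sd))))
                counts = simulate_assay(a, n_worms, params.immobile_prob, rng)
                assays.append(AssayReplicate(
                    patient_id=pid, dilution=params.dilution, counts=counts,
                    block=f"block{(len(assays)) // 6 + 1:03d}",
                    replicate_index=r + 1,
                ))
            psa = _draw_truncated_lognormal(psa_mu, psa_sigma, *PSA_WINDOW, rng)
            age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 45, 75))
            bmi = float(max(15.0, rng.normal(params.bmi_mean, params.bmi_sd)))
            prostate = float(max(10.0, rng.normal(params.prostate_mean[group],
                                                  params.prostate_sd)))
            smoker = bool(rng.uniform() < params.smoking_prevalence)
            gleason = None
            if group == "cancer":
                gleason = "low" if rng.uniform() < params.gleason_low_prob else "high"
            patients.append(PatientRecord(
                patient_id=pid, group=group, psa_ng_ml=round(psa, 2),
                age_years=round(age, 1), bmi=round(bmi, 1),
                prostate_cm3=round(prostate, 1), smoker=smoker,
                gleason_cat=gleason,
            ))
    return SyntheticCohort(patients=patients, assays=assays, params=params,
                           seed=seed, latent_attraction=latent)


def simulate_dilution_screen(
    params: SimulationParams,
    seed: int | None = None,
    n_per_group: int = 4,
    dilution_effect: dict[str, float] | None = None,
) -> SyntheticCohort:
    """Simulate the preliminary serial-dilution screen.

    A small panel (default 4 patients per group) is assayed at every dilution
    in the series.  ``dilution_effect`` scales each group's mean attraction
    per dilution; the default carries the full group effect only at 1:100 and
    strongly attenuated effects elsewhere, emulating a dilution-dependent
    behavioral response where a single dilution discriminates.
    """
    if seed is None:
        seed = params.seed
    if dilution_effect is None:
        dilution_effect = {d: (1.0 if d == "1:100" else 0.1) for d in DILUTIONS}
    if len(dilution_effect) < 2:
        raise ValueError("dilution screen needs >= 2 dilutions")
    rng = np.random.default_rng(seed)
    small = {g: min(n_per_group, params.n_per_group.get(g, n_per_group))
             for g in GROUPS}
    patients: list[PatientRecord] = []
    assays: list[AssayReplicate] = []
    latent: dict[str, float] = {}
    rep_ks = sorted(params.replicate_probs)
    rep_ps = [params.replicate_probs[k] for k in rep_ks]
    prefix = {"negative_screen": "N", "benign": "B", "cancer": "C"}
    for group in GROUPS:
        mu_a = params.mean_attraction[group]
        psa_mu, psa_sigma = params.psa_params[group]
        for i in range(small[group]):
            pid = f"{prefix[group]}{i + 1:02d}"
            # shared patient-level deviation; dilution scales the group effect
            dev = rng.normal(0.0, params.between_patient_sd)
            psa = _draw_truncated_lognormal(psa_mu, psa_sigma, *PSA_WINDOW, rng)
            patients.append(PatientRecord(
                patient_id=pid, group=group, psa_ng_ml=round(psa, 2),
                age_years=63.0, bmi=28.0, prostate_cm3=None, smoker=False,
                gleason_cat=None,
            ))
            for dil, scale in dilution_effect.items():
                l0 = logit((1.0 + mu_a * scale) / 2.0)
                a = float(2.0 * expit(l0 + dev) - 1.0)
                latent[f"{pid}@{dil}"] = a
                n_reps = int(rng.choice(rep_ks, p=rep_ps))
                for r in range(n_reps):
                    n_worms = max(1, int(round(rng.normal(params.n_worms_mean,
                                                          params.n_worms_sd))))
                    counts = simulate_assay(a, n_worms, params.immobile_prob, rng)
                    assays.append(AssayReplicate(
                        patient_id=pid, dilution=dil, counts=counts,
                        block="screen", replicate_index=r + 1,
                    ))
    return SyntheticCohort(patients=patients, assays=assays, params=params,
                           seed=seed, latent_attraction=latent)


def estimate_attraction(replicates: list[QuadrantCounts]) -> float:
    """Mean CI across plates: the natural estimator of the attraction parameter.

    Used by parameter-recovery checks; degenerate plates (no scored worms)
    are skipped.
    """
    cis = [compute_ci(c) for c in replicates if c.scored > 0]
    if not cis:
        raise UndefinedCIError("all replicates degenerate: attraction inestimable")
    return float(np.mean(cis))
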