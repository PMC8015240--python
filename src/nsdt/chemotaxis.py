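"""Chemotaxis index (CI) computation and technical-replicate aggregation.

The quadrant chemotaxis assay scores worm migration on an agar plate divided
into two diagonally opposed test quadrants (T1, T2, spotted with sample) and
two control quadrants (C1, C2, spotted with diluent).  Worms remaining inside
the 1 cm circle at the plate center are treated as immobile or anosmic and are
excluded from scoring.  The chemotaxis index of one plate is

    CI = ((T1 + T2) - (C1 + C2)) / (T1 + T2 + C1 + C2)

so CI = +1 means pure attraction, -1 pure repulsion, and 0 no preference.
One plate is a technical replicate; 4-6 replicate CIs are averaged to one CI
per patient urine sample (the biological replicate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "QuadrantCounts",
    "AssayReplicate",
    "PatientCI",
    "UndefinedCIError",
    "compute_ci",
    "subsample_replicates",
    "aggregate_patient",
    "qc_positive_control",
]


class UndefinedCIError(ValueError):
    """Raised when a plate has no scored worms (all in the center circle)."""


@dataclass(frozen=True)
class QuadrantCounts:
    """Worm tallies for one plate.

    ``center`` counts worms inside the 1 cm center circle; they never enter
    the CI computation.
    """

    t1: int
    t2: int
    c1: int
    c2: int
    center: int = 0

    def __post_init__(self) -> None:
        for name in ("t1", "t2", "c1", "c2", "center"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def scored(self) -> int:
        """Worms outside the center circle (the CI denominator)."""
        return self.t1 + self.t2 + self.c1 + self.c2

    @property
    def total(self) -> int:
        return self.scored + self.center


@dataclass
class AssayReplicate:
    """One technical replicate: a completed plate assay for one sample."""

    patient_id: str
    dilution: str
    counts: QuadrantCounts
    block: str = ""
    replicate_index: int = 0

    @property
    def ci(self) -> float | None:
        """Plate CI, or None for a degenerate plate (no scored worms)."""
        if self.counts.scored == 0:
            return None
        return compute_ci(self.counts)


@dataclass
class PatientCI:
    """Aggregated chemotaxis index for one patient (biological replicate)."""

    patient_id: str
    replicate_cis: list[float]
    mean_ci: float
    sem_ci: float
    n_used: int
    n_excluded: int = 0


def compute_ci(counts: QuadrantCounts) -> float:
    """Chemotaxis index of one plate.

    Parameters
    ----------
    counts
        Quadrant tallies. ``counts.scored`` must be positive.

    Returns
    -------
    float
        ((t1+t2) - (c1+c2)) / (t1+t2+c1+c2), in [-1, 1]. The center count
        is ignored.

    Raises
    ------
    UndefinedCIError
        If no worms left the center circle.
    """
    scored = counts.scored
    if scored == 0:
        raise UndefinedCIError(
            "CI undefined: no scored worms (all worms in center circle)"
        )
    return ((counts.t1 + counts.t2) - (counts.c1 + counts.c2)) / scored


def subsample_replicates(
    replicates: list[AssayReplicate],
    k: int = 6,
    rng: np.random.Generator | None = None,
) -> list[AssayReplicate]:
    """Cap the technical replicates of one sample at ``k`` by random subsampling.

    Some samples were assayed more than six times; to prevent skewed
    oversampling, ``k`` replicates are drawn uniformly without replacement
    when more than ``k`` are available.  With ``k`` or fewer, the input is
    returned unchanged.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not replicates:
        raise ValueError("no replicates to subsample")
    if len(replicates) <= k:
        return list(replicates)
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.choice(len(replicates), size=k, replace=False)
    return [replicates[i] for i in sorted(idx)]


def aggregate_patient(replicates: list[AssayReplicate]) -> PatientCI:
    """Average technical-replicate CIs to one CI per patient.

    Degenerate plates (no scored worms) are excluded and logged; the SEM uses
    the sample (n-1) standard deviation, matching mean±s.e.m. reporting.

    Raises
    ------
    UndefinedCIError
        If every replicate is degenerate, or the list is empty.
    """
    if not replicates:
        raise UndefinedCIError("no replicates to aggregate")
    cis: list[float] = []
    n_excluded = 0
    for rep in replicates:
        ci = rep.ci
        if ci is None:
            n_excluded += 1
            logger.warning(
                "patient %s: degenerate plate (replicate %d, block %s) excluded",
                rep.patient_id, rep.replicate_index, rep.block,
            )
        else:
            cis.append(ci)
    if not cis:
        raise UndefinedCIError(
            f"patient {replicates[0].patient_id}: all replicates degenerate"
        )
    n = len(cis)
    mean = float(np.mean(cis))
    sem = float(np.std(cis, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return PatientCI(
        patient_id=replicates[0].patient_id,
        replicate_cis=cis,
        mean_ci=mean,
        sem_ci=sem,
        n_used=n,
        n_excluded=n_excluded,
    )


@dataclass
class QCResult:
    """Outcome of a positive-control check for one assay block."""

    passed: bool
    mean_ci: float
    n: int
    verified: bool = True  # False when fewer than 3 control replicates ran


def qc_positive_control(
    control_replicates: list[AssayReplicate],
    min_mean_ci: float = 0.5,
) -> QCResult:
    """Check an assay block's isoamyl-alcohol positive control.

    Each block runs at least three plates with a known strong attractant; the
    block passes iff the mean control CI is >= ``min_mean_ci`` (inclusive).
    With fewer than three control plates the block is marked unverified (a
    warning, not a failure).
    """
    cis = [r.ci for r in control_replicates if r.ci is not None]
    if not cis:
        raise UndefinedCIError("no usable positive-control replicates")
    mean = float(np.mean(cis))
    verified = len(cis) >= 3
    if not verified:
        logger.warning(
            "positive control has only %d replicates (<3): block unverified",
            len(cis),
        )
    return QCResult(passed=mean >= min_mean_ci, mean_ci=mean, n=len(cis),
                    verified=verified)
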