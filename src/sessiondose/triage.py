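"""Support-level triage of individual model fits.

Individual weighted residuals (IWRES) turn each residual into a z-score by
dividing by the residual SD of the additive error model.  Baseline (time 0)
observations are excluded — the model is initialised at the observed severe
level, so their residuals are identically zero and carry no information.
A patient with fewer than two post-baseline observations cannot be
classified; otherwise the absolute mean and the sample SD of the IWRES are
graded separately and the worse grade wins:

    |mean|: <=1 supported, (1, 1.5] semi-supported, >1.5 unsupported
    SD:     <=1.5 supported, (1.5, 2] semi-supported, >2 unsupported

The worse-of-two combination is a deliberately cautious rule: either an
offset fit or an erratic one is enough to flag a patient for review.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .estimation import FitResult, PatientFit
from .model import ValidationError

__all__ = [
    "SupportClass",
    "IwresSummary",
    "iwres",
    "summarize_iwres",
    "classify_support",
    "triage_cohort",
    "TriageReport",
]


class SupportClass(enum.Enum):
    SUPPORTED = "supported"
    SEMI_SUPPORTED = "semi_supported"
    UNSUPPORTED = "unsupported"
    UNCLASSIFIABLE = "unclassifiable"


# ordering for the worse-of-two-grades rule
_GRADE_ORDER = {SupportClass.SUPPORTED: 0, SupportClass.SEMI_SUPPORTED: 1,
                SupportClass.UNSUPPORTED: 2}


@dataclass(frozen=True)
class IwresSummary:
    """IWRES descriptives for one patient, baseline excluded."""

    iwres_values: np.ndarray
    mean_abs: float   # |mean(IWRES)|
    sd: float         # sample SD (n-1); nan when n_used < 2
    n_used: int

    @classmethod
    def from_values(cls, values) -> "IwresSummary":
        v = np.asarray(values, dtype=np.float64)
        n = v.size
        return cls(iwres_values=v,
                   mean_abs=float(abs(v.mean())) if n else float("nan"),
                   sd=float(v.std(ddof=1)) if n >= 2 else float("nan"),
                   n_used=n)


def iwres(residual: float, sigma: float) -> float:
    """Individual weighted residual: (observed - predicted) / sigma."""
    if not (np.isfinite(sigma) and sigma > 0):
        raise ValidationError(f"sigma must be finite and > 0, got {sigma}")
    return float(residual) / float(sigma)


def summarize_iwres(fit: PatientFit, sigma: float) -> IwresSummary:
    """IWRES summary for one fitted patient, excluding time-0 observations."""
    mask = fit.obs_times > 0
    values = fit.residuals[mask] / float(sigma)
    if not (np.isfinite(sigma) and sigma > 0):
        raise ValidationError(f"sigma must be finite and > 0, got {sigma}")
    return IwresSummary.from_values(values)


def _grade_mean(mean_abs: float) -> SupportClass:
    if mean_abs <= 1.0:
        return SupportClass.SUPPORTED
    if mean_abs <= 1.5:
        return SupportClass.SEMI_SUPPORTED
    return SupportClass.UNSUPPORTED


def _grade_sd(sd: float) -> SupportClass:
    if sd <= 1.5:
        return SupportClass.SUPPORTED
    if sd <= 2.0:
        return SupportClass.SEMI_SUPPORTED
    return SupportClass.UNSUPPORTED


def classify_support(summary: IwresSummary) -> SupportClass:
    """Support class from an IWRES summary (time-0 exclusion already applied).

    Thresholds are inclusive exactly as graded above; a value equal to a
    threshold takes the better class.  The mean and SD criteria are graded
    separately and the worse grade is returned.
    """
    if summary.n_used < 2:
        return SupportClass.UNCLASSIFIABLE
    g_mean = _grade_mean(summary.mean_abs)
    g_sd = _grade_sd(summary.sd)
    return max(g_mean, g_sd, key=_GRADE_ORDER.__getitem__)


@dataclass
class TriageReport:
    """Per-patient classes plus cohort tabulation on two percentage bases."""

    classes: dict[str, SupportClass]
    summaries: dict[str, IwresSummary]
    counts: dict[str, int]
    pct_total: dict[str, float]
    pct_classified: dict[str, float | None]

    def to_dict(self) -> dict:
        return {
            "classes": {k: v.value for k, v in self.classes.items()},
            "counts": dict(self.counts),
            "pct_total": dict(self.pct_total),
            "pct_classified": dict(self.pct_classified),
        }


def triage_cohort(fit: FitResult) -> TriageReport:
    """Classify every fitted patient and tabulate the cohort.

    Percentages are reported both over all patients and over classifiable
    patients only (the latter excludes the not-enough-data class).
    """
    sigma = fit.population.sigma
    classes: dict[str, SupportClass] = {}
    summaries: dict[str, IwresSummary] = {}
    for pf in fit.patients:
        s = summarize_iwres(pf, sigma)
        summaries[pf.patient_id] = s
        classes[pf.patient_id] = classify_support(s)

    counts = {c.value: 0 for c in SupportClass}
    for c in classes.values():
        counts[c.value] += 1
    total = len(classes)
    n_classified = total - counts[SupportClass.UNCLASSIFIABLE.value]
    pct_total = {k: (100.0 * v / total if total else 0.0)
                 for k, v in counts.items()}
    pct_classified = {
        k: (100.0 * v / n_classified if n_classified and
            k != SupportClass.UNCLASSIFIABLE.value else None)
        for k, v in counts.items()}
    return TriageReport(classes=classes, summaries=summaries, counts=counts,
                        pct_total=pct_total, pct_classified=pct_classified)
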