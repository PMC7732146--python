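"""Deterministic cardiometabolic risk classification and BP categorisation.

Five binary criteria (Asian-Indian thresholds) define the risk cluster:

1. central obesity — waist ≥ 90 cm (men) / ≥ 80 cm (women);
2. elevated triglycerides — TGL ≥ 150 mg/dL or on treatment;
3. reduced HDL-C — HDL < 40 mg/dL (men) / < 50 mg/dL (women) or on treatment;
4. high BP — SBP ≥ 130 or DBP ≥ 80 mmHg, or on antihypertensive treatment;
5. elevated fasting glucose — FPG > 100 mg/dL (strict) or on treatment.

Three or more criteria mark a subject "high risk" (the metabolic-syndrome
proxy used throughout the population statistics).  Blood-pressure categories
follow the ACC/AHA strata; when SBP and DBP indicate different categories the
higher category wins.  Boundary semantics (≥ vs >) are implemented exactly as
defined above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .errors import MissingDataError, ValidationError
from .synthgen import SubjectCovariates

__all__ = [
    "RiskProfile",
    "SmokingHistory",
    "AlcoholHistory",
    "classify_risks",
    "bp_category",
    "smoking_status",
    "alcohol_status",
    "BP_CATEGORIES",
]

BP_CATEGORIES = ("normal", "elevated", "stage1", "stage2", "crisis")


@dataclass(frozen=True)
class RiskProfile:
    """Per-subject risk flags, their count, and behavioural status."""

    central_obesity: bool
    elevated_tgl: bool
    reduced_hdl: bool
    high_bp: bool
    elevated_fpg: bool
    n_risks: int
    high_risk: bool
    bp_category: str
    smoking_status: str
    alcohol_status: str

    def __post_init__(self) -> None:
        flags = (
            self.central_obesity,
            self.elevated_tgl,
            self.reduced_hdl,
            self.high_bp,
            self.elevated_fpg,
        )
        if self.n_risks != sum(flags):
            raise ValidationError("n_risks must equal the count of true flags")
        if self.high_risk != (self.n_risks >= 3):
            raise ValidationError("high_risk must mean n_risks >= 3")


def bp_category(sbp: float, dbp: float) -> str:
    """ACC/AHA blood-pressure category; higher of the two component categories.

    normal: SBP < 120 and DBP < 80; elevated: SBP 120–129 and DBP < 80;
    stage1: SBP 130–139 or DBP 80–89; stage2: SBP ≥ 140 or DBP ≥ 90;
    crisis: SBP > 180 or DBP > 120.
    """
    if not sbp > dbp > 0:
        raise ValidationError(f"require SBP > DBP > 0, got {sbp}/{dbp}")
    if sbp > 180.0 or dbp > 120.0:
        return "crisis"
    if sbp >= 140.0 or dbp >= 90.0:
        return "stage2"
    if sbp >= 130.0 or dbp >= 80.0:
        return "stage1"
    if sbp >= 120.0:
        return "elevated"
    return "normal"


def classify_risks(subject: SubjectCovariates) -> RiskProfile:
    """Apply the five risk rules to one subject.

    BP inputs are the mean of the two replicate readings.  A missing HDL assay
    raises :class:`MissingDataError` (such subjects are excluded from risk
    analyses, mirroring field practice).
    """
    if subject.hdl is None or (isinstance(subject.hdl, float) and math.isnan(subject.hdl)):
        raise MissingDataError(f"{subject.subject_id}: HDL-C unavailable")
    male = subject.sex == "male"
    sbp, dbp = subject.sbp_mean, subject.dbp_mean
    central_obesity = subject.waist >= (90.0 if male else 80.0)
    elevated_tgl = subject.tgl >= 150.0 or subject.on_lipid_meds
    reduced_hdl = subject.hdl < (40.0 if male else 50.0) or subject.on_lipid_meds
    high_bp = sbp >= 130.0 or dbp >= 80.0 or subject.on_bp_meds
    elevated_fpg = subject.fpg > 100.0 or subject.on_glucose_meds
    n = sum((central_obesity, elevated_tgl, reduced_hdl, high_bp, elevated_fpg))
    return RiskProfile(
        central_obesity=central_obesity,
        elevated_tgl=elevated_tgl,
        reduced_hdl=reduced_hdl,
        high_bp=high_bp,
        elevated_fpg=elevated_fpg,
        n_risks=n,
        high_risk=n >= 3,
        bp_category=bp_category(sbp, dbp),
        smoking_status=subject.smoking_status,
        alcohol_status=subject.alcohol_status,
    )


@dataclass(frozen=True)
class SmokingHistory:
    """Raw questionnaire fields for tobacco use."""

    lifetime_cigarettes: int
    smokes_now: bool
    quit_previously: bool = False


@dataclass(frozen=True)
class AlcoholHistory:
    """Raw questionnaire fields for alcohol consumption."""

    ever_drank: bool
    drank_past_12mo: bool
    days_per_week: float = 0.0


def smoking_status(history: SmokingHistory) -> Literal["never", "former", "current"]:
    """Current: >100 lifetime cigarettes and still smoking (daily or
    occasionally); former: smoked but quit earlier; never otherwise."""
    if history.smokes_now and history.quit_previously:
        raise ValidationError("contradictory smoking history: quit but currently smoking")
    if history.lifetime_cigarettes > 100 and history.smokes_now:
        return "current"
    if history.quit_previously and history.lifetime_cigarettes > 0:
        return "former"
    return "never"


def alcohol_status(
    history: AlcoholHistory,
) -> Literal["never", "former", "current", "regular"]:
    """Current: any alcohol in the past 12 months; regular: ≥ 1 day/week;
    former: drank before but not in the past 12 months; never otherwise."""
    if history.days_per_week > 0 and not history.drank_past_12mo:
        raise ValidationError("contradictory alcohol history: weekly use but none in 12 months")
    if history.days_per_week < 0:
        raise ValidationError("days_per_week must be >= 0")
    if history.drank_past_12mo:
        return "regular" if history.days_per_week >= 1.0 else "current"
    if history.ever_drank:
        return "former"
    return "never"
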