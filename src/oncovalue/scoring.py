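"""Advanced-disease value framework, Steps 1-4.

Step 1 (clinical benefit) walks a fixed evidence hierarchy: death hazard
ratio, then median overall survival, then progression hazard ratio, then
median progression-free survival, then response rate.  Only the highest
available rung is scored; from a death HR the score is (1 - HR) x 100.
Lower rungs apply the framework's scaling multipliers.

Step 2 (toxicity) sums per-adverse-event points (0.5/1 for grades 1-2 below/
at-or-above 10%; 1.5/2 for grades 3-4 below/at-or-above 5%) per arm, then
scores (1 - test/comparator) x 20 — negative when the test regimen is more
toxic.

Step 3 (bonus) awards up to 20 tail-of-the-curve points when the surviving
proportion on the test arm at twice the comparator's median is at least 50%
greater (with more than 20% surviving on the comparator), and 10 points each
for statistically significant palliation, quality-of-life and
treatment-free-interval findings.

Step 4 sums the three components into the net health benefit (NHB).

Component rounding
------------------
Scores are truncated toward zero at ``component_decimals`` (default 2) before
summation.  Truncation, not half-up rounding, is what reproduces the published
worked scorecards: (1 - 27/22) x 20 = -4.5454... is printed as -4.54.  A tiny
half-even pre-round at 9 decimals absorbs binary floating-point noise so that
exact decimal ratios (e.g. 44.5/40) truncate to their true value.
"""

from __future__ import annotations

import logging
from decimal import ROUND_DOWN, ROUND_HALF_EVEN, Decimal
from typing import NamedTuple, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .config import ScoringConfig
from .errors import NoEfficacyEvidenceError, UndefinedRatioError
from .evidence import (
    BonusEvidence,
    EfficacyEvidence,
    GradeBand,
    TailOfCurveEvidence,
    ToxicityProfile,
)

logger = logging.getLogger(__name__)

__all__ = [
    "round_component",
    "clinical_benefit_score",
    "ae_entry_points",
    "toxicity_points_total",
    "toxicity_score",
    "tail_of_curve_bonus",
    "categorical_bonus",
    "net_health_benefit",
    "ClinicalBenefit",
    "TailVerdict",
    "BonusBreakdown",
    "NetHealthBenefit",
]


def round_component(x: float, decimals: int = 2) -> float:
    """Truncate ``x`` toward zero at ``decimals`` decimal places.

    Floating-point noise is absorbed by a half-even pre-round at 9 decimals,
    so values that are exact in decimal arithmetic are never truncated past
    their true value.
    """
    d = Decimal(repr(float(x))).quantize(Decimal("1e-9"), rounding=ROUND_HALF_EVEN)
    return float(d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_DOWN))


class ClinicalBenefit(NamedTuple):
    points: float
    rung: str  # which hierarchy rung produced the score: "1.A" .. "1.E"


def clinical_benefit_score(
    efficacy: EfficacyEvidence, config: ScoringConfig
) -> ClinicalBenefit:
    """Step 1: score the highest available rung of the efficacy hierarchy.

    Returns the score (truncated at ``config.component_decimals``) together
    with the rung used.  A hazard ratio above 1 yields a negative score; harm
    is reported, not clamped.
    """
    m = config.benefit_multipliers
    dec = config.component_decimals
    if efficacy.death_hr is not None:
        raw = (1.0 - efficacy.death_hr.point) * 100.0 * m.os_hr
        rung = "1.A"
    elif efficacy.median_os is not None:
        e = efficacy.median_os
        if e.median_comparator <= 0:
            raise UndefinedRatioError("median OS of comparator must be positive")
        raw = 100.0 * (e.median_test - e.median_comparator) / e.median_comparator * m.median_os
        rung = "1.B"
    elif efficacy.progression_hr is not None:
        raw = (1.0 - efficacy.progression_hr.point) * 100.0 * m.pfs_hr
        rung = "1.C"
    elif efficacy.median_pfs is not None:
        e = efficacy.median_pfs
        if e.median_comparator <= 0:
            raise UndefinedRatioError("median PFS of comparator must be positive")
        raw = 100.0 * (e.median_test - e.median_comparator) / e.median_comparator * m.median_pfs
        rung = "1.D"
    elif efficacy.response is not None:
        e = efficacy.response
        raw = 100.0 * (e.rr_test - e.rr_comparator) * m.rr
        rung = "1.E"
    else:  # unreachable for validated evidence
        raise NoEfficacyEvidenceError("no efficacy evidence available")
    score = round_component(raw, dec)
    if score < 0:
        logger.warning("clinical benefit is negative (%s): test regimen appears harmful", score)
    logger.info("clinical benefit %.4g points from rung %s", score, rung)
    return ClinicalBenefit(points=score, rung=rung)


def ae_entry_points(grade_band: GradeBand, frequency: float, config: ScoringConfig) -> float:
    """Points for a single adverse event given its grade band and frequency."""
    if not 0.0 <= frequency <= 1.0:
        raise ValueError(f"frequency must be in [0, 1], got {frequency}")
    band = GradeBand(grade_band)
    if band is GradeBand.g1_2:
        return (
            config.low_grade_minor_points
            if frequency < config.low_grade_threshold
            else config.low_grade_major_points
        )
    return (
        config.high_grade_minor_points
        if frequency < config.high_grade_threshold
        else config.high_grade_major_points
    )


def toxicity_points_total(profile: ToxicityProfile, config: ScoringConfig) -> float:
    """Total adverse-event points for one arm.

    A ``precomputed_total`` (published totals whose itemization is not
    available) takes precedence over itemized entries.
    """
    if profile.precomputed_total is not None:
        return profile.precomputed_total
    return sum(ae_entry_points(e.grade_band, e.frequency, config) for e in profile.entries)


def toxicity_score(test_total: float, comparator_total: float, config: ScoringConfig) -> float:
    """Step 2: (1 - test/comparator) x multiplier, truncated at 2 decimals.

    Negative exactly when the test regimen is the more toxic arm.
    """
    if comparator_total <= 0:
        raise UndefinedRatioError(
            f"comparator toxicity total must be positive, got {comparator_total}"
        )
    raw = (1.0 - test_total / comparator_total) * config.toxicity_multiplier
    return round_component(raw, config.component_decimals)


class TailVerdict(NamedTuple):
    points: float
    eligible: bool
    reason: str


def tail_of_curve_bonus(
    tail: Optional[TailOfCurveEvidence], config: ScoringConfig
) -> TailVerdict:
    """Step 3.A: tail-of-the-curve bonus with an explicit eligibility verdict.

    Eligibility requires survival proportions at twice the comparator's
    median, more than ``tail_comparator_floor`` surviving on the comparator,
    and a relative improvement of at least ``tail_improvement_threshold``.
    When eligible, the points are ``awarded_points`` if supplied (clamped to
    the 0..``tail_max_points`` range) else the full maximum — the framework
    states "up to 20 points" without a magnitude formula.
    """
    if tail is None:
        return TailVerdict(0.0, False, "not_reported")
    expected = 2.0 * tail.comparator_median
    if abs(tail.assessment_time - expected) > 0.05 * expected:
        logger.warning(
            "tail assessment time %.3g differs from twice the comparator median (%.3g) by >5%%",
            tail.assessment_time,
            expected,
        )
    if tail.prop_comparator <= config.tail_comparator_floor:
        return TailVerdict(0.0, False, "comparator_survival_at_or_below_floor")
    improvement = (tail.prop_test - tail.prop_comparator) / tail.prop_comparator
    if improvement < config.tail_improvement_threshold:
        return TailVerdict(0.0, False, "improvement_below_threshold")
    if tail.awarded_points is not None:
        pts = min(max(tail.awarded_points, 0.0), config.tail_max_points)
    else:
        pts = config.tail_max_points
    return TailVerdict(pts, True, "eligible")


class BonusBreakdown(BaseModel):
    """Step 3E: the four bonus components and their exact sum."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    tail_points: float
    palliation_points: float
    qol_points: float
    tfi_points: float
    total: float

    @model_validator(mode="after")
    def _total_exact(self) -> "BonusBreakdown":
        s = self.tail_points + self.palliation_points + self.qol_points + self.tfi_points
        if self.total != s:
            raise ValueError(f"bonus total {self.total} != component sum {s}")
        return self


def categorical_bonus(bonus: BonusEvidence, config: ScoringConfig) -> BonusBreakdown:
    """Step 3: assemble the bonus breakdown.

    Palliation, quality of life and treatment-free interval each contribute
    their configured points iff the corresponding significance flag is true;
    an absent flag means "not reported" and scores 0.
    """
    tail = tail_of_curve_bonus(bonus.tail, config)
    pall = config.palliation_points if bonus.palliation_significant else 0.0
    qol = config.qol_points if bonus.qol_significant else 0.0
    tfi = config.tfi_points if bonus.tfi_significant else 0.0
    total = tail.points + pall + qol + tfi
    return BonusBreakdown(
        tail_points=tail.points,
        palliation_points=pall,
        qol_points=qol,
        tfi_points=tfi,
        total=total,
    )


class NetHealthBenefit(BaseModel):
    """Step 4: the composite score and its components."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    clinical_benefit: float
    toxicity_score: float
    bonus: BonusBreakdown
    nhb: float
    max_possible: float

    @model_validator(mode="after")
    def _additive(self) -> "NetHealthBenefit":
        s = self.clinical_benefit + self.toxicity_score + self.bonus.total
        if self.nhb != s:
            raise ValueError(f"nhb {self.nhb} != component sum {s}")
        return self


def net_health_benefit(
    clinical_benefit: float,
    toxicity: float,
    bonus: BonusBreakdown,
    config: ScoringConfig,
) -> NetHealthBenefit:
    """Step 4: NHB = clinical benefit + toxicity score + bonus total (exact).

    Components are expected to be already rounded per the configured
    convention; the sum itself is not rounded further.
    """
    nhb = clinical_benefit + toxicity + bonus.total
    if nhb > config.max_nhb:
        logger.warning("NHB %.4g exceeds the nominal maximum of %g", nhb, config.max_nhb)
    return NetHealthBenefit(
        clinical_benefit=clinical_benefit,
        toxicity_score=toxicity,
        bonus=bonus,
        nhb=nhb,
        max_possible=config.max_nhb,
    )
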