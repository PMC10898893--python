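"""Domain types for two-arm trial evidence summaries.

The unit the pipeline scores is a :class:`TrialEvidence`: one test-regimen vs
comparator comparison carrying efficacy estimates (a hierarchy of hazard
ratios, medians and response rates), per-arm toxicity profiles (itemized
graded adverse-event frequencies or a precomputed point total) and the
evidence behind the bonus components (tail of the survival curve, palliation,
quality of life, treatment-free interval).

All models are strict: unknown fields are rejected and the invariants below
(CI ordering, proportions in [0, 1], non-negative point totals) are enforced
at construction, so anything downstream can assume a valid object.
"""

from __future__ import annotations

import enum
import warnings
from typing import Optional

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

SCHEMA_VERSION = "oncovalue-trial/1"


class Endpoint(str, enum.Enum):
    overall_survival = "overall_survival"
    progression_free_survival = "progression_free_survival"


class GradeBand(str, enum.Enum):
    g1_2 = "g1_2"
    g3_4 = "g3_4"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class HazardRatioEstimate(_Strict):
    """A hazard ratio with its 95% confidence interval."""

    point: float = Field(gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float = Field(gt=0)
    endpoint: Endpoint

    @model_validator(mode="after")
    def _ci_ordered(self) -> "HazardRatioEstimate":
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"confidence interval must satisfy ci_low <= point <= ci_high, "
                f"got ci_low={self.ci_low}, point={self.point}, ci_high={self.ci_high}"
            )
        return self


class MedianEstimate(_Strict):
    median_test: float = Field(ge=0, description="months")
    median_comparator: float = Field(ge=0, description="months")
    endpoint: Endpoint


class ResponseRates(_Strict):
    rr_test: float = Field(ge=0, le=1)
    rr_comparator: float = Field(ge=0, le=1)


class EfficacyEvidence(_Strict):
    """Evidence for the clinical-benefit hierarchy, highest rung first.

    At least one field must be present; the scorer uses the highest-priority
    rung available (death HR > median OS > progression HR > median PFS > RR).
    """

    death_hr: Optional[HazardRatioEstimate] = None
    median_os: Optional[MedianEstimate] = None
    progression_hr: Optional[HazardRatioEstimate] = None
    median_pfs: Optional[MedianEstimate] = None
    response: Optional[ResponseRates] = None

    @model_validator(mode="after")
    def _some_evidence(self) -> "EfficacyEvidence":
        if all(
            getattr(self, f) is None
            for f in ("death_hr", "median_os", "progression_hr", "median_pfs", "response")
        ):
            raise ValueError("at least one efficacy field must be present")
        return self


class AdverseEventEntry(_Strict):
    term: str
    grade_band: GradeBand
    frequency: float = Field(ge=0, le=1)

    @field_validator("grade_band", mode="before")
    @classmethod
    def _map_grade5(cls, v):
        # the framework covers grades 1-4 only; grade-5 events are folded
        # into the high-grade band rather than dropped
        if isinstance(v, str) and v.strip().lower() in {"g5", "grade5", "grade_5"}:
            warnings.warn(
                "grade-5 adverse event mapped to the g3_4 band "
                "(framework covers grades 1-4 only)",
                stacklevel=2,
            )
            return GradeBand.g3_4
        return v


class ToxicityProfile(_Strict):
    """Per-arm adverse events, itemized and/or as a precomputed point total.

    An empty profile (no entries, no precomputed total) is valid and scores
    zero points.
    """

    entries: list[AdverseEventEntry] = Field(default_factory=list)
    precomputed_total: Optional[float] = Field(default=None, ge=0)


class TailOfCurveEvidence(_Strict):
    """Survival proportions at twice the comparator's median."""

    comparator_median: float = Field(gt=0, description="months")
    assessment_time: float = Field(gt=0, description="months")
    prop_test: float = Field(ge=0, le=1)
    prop_comparator: float = Field(ge=0, le=1)
    awarded_points: Optional[float] = Field(default=None, ge=0, le=20)


class BonusEvidence(_Strict):
    """Bonus-component evidence; an absent component scores 0."""

    tail: Optional[TailOfCurveEvidence] = None
    palliation_significant: Optional[bool] = None
    qol_significant: Optional[bool] = None
    tfi_significant: Optional[bool] = None
    notes: dict[str, str] = Field(default_factory=dict)


class TrialEvidence(_Strict):
    trial_name: str = Field(min_length=1)
    test_label: str = Field(min_length=1)
    comparator_label: str = Field(min_length=1)
    efficacy: EfficacyEvidence
    toxicity_test: ToxicityProfile
    toxicity_comparator: ToxicityProfile
    bonus: BonusEvidence = Field(default_factory=BonusEvidence)
    # some published scorecards print a toxicity score inconsistent with
    # their own printed point totals; both are stored and neither is
    # silently preferred (see scoring provenance)
    reported_toxicity_score: Optional[float] = None
    metadata: dict[str, str] = Field(default_factory=dict)
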