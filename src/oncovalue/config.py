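"""Framework constants in one versioned, hashable place.

Every numeric constant of the advanced-disease value framework lives in
:class:`ScoringConfig` so that a scorecard can record exactly which rule set
produced it.  Defaults reproduce the published framework: per-event toxicity
points keyed on grade band and frequency thresholds (10% for grades 1-2, 5%
for grades 3-4), a toxicity multiplier of 20, benefit-hierarchy multipliers,
bonus point values (tail of the curve up to 20; palliation, quality of life
and treatment-free interval 10 each) and the 180-point nominal maximum.

``cop_per_usd`` and ``days_per_month`` are plumbing for the cost model: the
exchange rate is back-solved from published COP/USD pairs (no rate or date is
stated alongside them) and a treatment month is 30 days (120 tablets at 4/day).
"""

from __future__ import annotations

import hashlib
import json

from pydantic import BaseModel, ConfigDict, Field


class BenefitMultipliers(BaseModel):
    """Scaling applied at each rung of the clinical-benefit hierarchy."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    os_hr: float = 1.0
    median_os: float = 1.0
    pfs_hr: float = 0.8
    median_pfs: float = 0.8
    rr: float = 0.7


class ScoringConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    # toxicity: per-adverse-event points by grade band and frequency
    low_grade_minor_points: float = Field(default=0.5, ge=0)
    low_grade_major_points: float = Field(default=1.0, ge=0)
    low_grade_threshold: float = Field(default=0.10, gt=0, lt=1)
    high_grade_minor_points: float = Field(default=1.5, ge=0)
    high_grade_major_points: float = Field(default=2.0, ge=0)
    high_grade_threshold: float = Field(default=0.05, gt=0, lt=1)
    toxicity_multiplier: float = Field(default=20.0, ge=0)

    benefit_multipliers: BenefitMultipliers = BenefitMultipliers()

    # bonus points
    tail_improvement_threshold: float = Field(default=0.50, gt=0)
    tail_comparator_floor: float = Field(default=0.20, gt=0, lt=1)
    tail_max_points: float = Field(default=20.0, ge=0)
    palliation_points: float = Field(default=10.0, ge=0)
    qol_points: float = Field(default=10.0, ge=0)
    tfi_points: float = Field(default=10.0, ge=0)

    max_nhb: float = Field(default=180.0, gt=0)
    component_decimals: int = Field(default=2, ge=0)

    # cost-model plumbing
    cop_per_usd: float = Field(default=3915.3, gt=0)
    days_per_month: int = Field(default=30, ge=28)

    def config_hash(self) -> str:
        """Stable short hash of the effective configuration (provenance)."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


DEFAULT_CONFIG = ScoringConfig()
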