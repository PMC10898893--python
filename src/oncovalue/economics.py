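"""Steps 5-6: monthly drug cost, cost per NHB point and the summary scorecard.

The cost model covers drug acquisition only: regulated price per mg times the
daily dose times a 30-day treatment month, in Colombian pesos (COP).  The
headline value-for-money metric is the monthly cost divided by the net health
benefit.  USD equivalents use a configurable exchange rate.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Literal, Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .config import ScoringConfig
from .errors import NonPositiveBenefitError, SchemaValidationError
from .evidence import TrialEvidence
from .scoring import (
    BonusBreakdown,
    NetHealthBenefit,
    categorical_bonus,
    clinical_benefit_score,
    net_health_benefit,
    tail_of_curve_bonus,
    toxicity_points_total,
    toxicity_score,
)

PathLike = Union[str, Path]

ToxicitySource = Literal["reported", "computed"]


class RegimenDosing(BaseModel):
    """Dosing and regulated unit price for one regimen."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    regimen_name: str = Field(min_length=1)
    tablet_strength: float = Field(gt=0, description="mg per tablet")
    daily_dose: float = Field(ge=0, description="mg per day")
    price_per_mg: float = Field(ge=0, description="COP per mg")
    currency: str = "COP"

    def model_post_init(self, __context) -> None:
        ratio = self.daily_dose / self.tablet_strength  # tablet_strength > 0
        if abs(ratio - round(ratio)) > 1e-9:
            warnings.warn(
                f"daily dose {self.daily_dose} mg is not a whole number of "
                f"{self.tablet_strength} mg tablets; tablet counts are ceiled",
                stacklevel=2,
            )


def monthly_drug_cost(dosing: RegimenDosing, config: ScoringConfig) -> float:
    """Step 5: price/mg x mg/day x days/month, rounded to whole COP."""
    if dosing.price_per_mg < 0:
        raise ValueError("price_per_mg must be non-negative")
    return float(round(dosing.price_per_mg * dosing.daily_dose * config.days_per_month))


def tablets_per_month(dosing: RegimenDosing, config: ScoringConfig) -> int:
    """Tablets dispensed per treatment month (daily count ceiled to whole tablets)."""
    per_day = math.ceil(dosing.daily_dose / dosing.tablet_strength - 1e-9)
    return per_day * config.days_per_month


def cost_per_nhb_point(monthly_cost: float, nhb: float) -> float:
    """Monthly cost divided by NHB, rounded to whole COP; undefined for NHB <= 0."""
    if nhb <= 0:
        raise NonPositiveBenefitError(
            f"cost per point is undefined for non-positive net health benefit ({nhb})"
        )
    return float(round(monthly_cost / nhb))


def to_usd(amount: float, config: ScoringConfig) -> float:
    """Convert a COP amount to USD at the configured rate, rounded to cents."""
    if config.cop_per_usd <= 0:
        raise ValueError("cop_per_usd must be positive")
    return round(amount / config.cop_per_usd, 2)


class ValueScorecard(BaseModel):
    """The Step-6 summary row plus full provenance."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    trial_name: str
    regimen_name: str
    nhb: NetHealthBenefit
    monthly_cost: float
    monthly_cost_usd: float
    cost_per_point: float
    cost_per_point_usd: float
    provenance: dict


def build_scorecard(
    trial: TrialEvidence,
    dosing: RegimenDosing,
    config: Optional[ScoringConfig] = None,
    toxicity_source: ToxicitySource = "reported",
) -> ValueScorecard:
    """Run Steps 1-5 and assemble the Step-6 summary row.

    ``toxicity_source`` selects between the toxicity score computed from the
    point totals and a ``reported_toxicity_score`` carried on the trial (some
    published scorecards print a score inconsistent with their own totals).
    The default "reported" falls back to the computed score when no reported
    value exists; whenever both exist and disagree, both are recorded in the
    provenance block and a warning is emitted — the choice is never silent.
    """
    config = config or ScoringConfig()
    cb = clinical_benefit_score(trial.efficacy, config)
    test_total = toxicity_points_total(trial.toxicity_test, config)
    comp_total = toxicity_points_total(trial.toxicity_comparator, config)
    computed_tox = toxicity_score(test_total, comp_total, config)
    reported_tox = trial.reported_toxicity_score
    conflict = reported_tox is not None and reported_tox != computed_tox
    if conflict:
        warnings.warn(
            f"{trial.trial_name}: reported toxicity score {reported_tox} disagrees with "
            f"the score computed from point totals ({computed_tox}); using the "
            f"{toxicity_source} value",
            stacklevel=2,
        )
    if toxicity_source == "reported" and reported_tox is not None:
        tox = reported_tox
    else:
        tox = computed_tox
    tail = tail_of_curve_bonus(trial.bonus.tail, config)
    bonus: BonusBreakdown = categorical_bonus(trial.bonus, config)
    nhb = net_health_benefit(cb.points, tox, bonus, config)
    cost = monthly_drug_cost(dosing, config)
    cpp = cost_per_nhb_point(cost, nhb.nhb)
    provenance = {
        "config_hash": config.config_hash(),
        "benefit_rung": cb.rung,
        "efficacy": trial.efficacy.model_dump(mode="json", exclude_none=True),
        "toxicity_points_test": test_total,
        "toxicity_points_comparator": comp_total,
        "toxicity_score_computed": computed_tox,
        "toxicity_score_reported": reported_tox,
        "toxicity_source": toxicity_source,
        "toxicity_conflict": conflict,
        "tail_eligible": tail.eligible,
        "tail_reason": tail.reason,
        "tablets_per_month": tablets_per_month(dosing, config),
    }
    return ValueScorecard(
        trial_name=trial.trial_name,
        regimen_name=dosing.regimen_name,
        nhb=nhb,
        monthly_cost=cost,
        monthly_cost_usd=to_usd(cost, config),
        cost_per_point=cpp,
        cost_per_point_usd=to_usd(cpp, config),
        provenance=provenance,
    )


DOSING_CSV_COLUMNS = [
    "regimen_name",
    "tablet_strength_mg",
    "daily_dose_mg",
    "price_per_mg",
    "currency",
]


def load_dosing(path: PathLike) -> RegimenDosing:
    """Read a dosing record from JSON ({field: value}) or single-row CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dosing file not found: {path}")
    if path.suffix.lower() == ".json":
        import json

        doc = json.loads(path.read_text(encoding="utf-8"))
        return RegimenDosing.model_validate(doc)
    df = pd.read_csv(path)
    missing = [c for c in DOSING_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaValidationError(f"dosing CSV missing columns: {missing}", "/")
    row = df.iloc[0]
    return RegimenDosing(
        regimen_name=str(row["regimen_name"]),
        tablet_strength=float(row["tablet_strength_mg"]),
        daily_dose=float(row["daily_dose_mg"]),
        price_per_mg=float(row["price_per_mg"]),
        currency=str(row["currency"]),
    )
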