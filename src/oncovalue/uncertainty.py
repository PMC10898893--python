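"""Monte-Carlo propagation of hazard-ratio uncertainty into NHB intervals.

The published scorecards carry 95% confidence intervals on the hazard ratios
but propagate only the point estimates.  This module is an extension: it
draws the HR from the standard meta-analytic log-normal, with standard error
(ln(ci_high) - ln(ci_low)) / (2 x 1.959964) and centred at the geometric mean
of the CI bounds — the unique log-normal whose 2.5/97.5% quantiles are exactly
the reported interval.  (For a CI symmetric in logs around the point estimate
this centre equals ln(point); reported values are rounded, so the two can
differ slightly.)  Each draw is mapped through the full scorecard with
toxicity and bonus held fixed (no uncertainty distributions exist for them).
Because the net health benefit is an affine, strictly decreasing function of
the HR, its p-quantile equals the scorecard evaluated at the HR
(1-p)-quantile.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .config import ScoringConfig
from .economics import RegimenDosing, ToxicitySource, monthly_drug_cost, toxicity_points_total, toxicity_score
from .errors import NoEfficacyEvidenceError
from .evidence import HazardRatioEstimate, TrialEvidence
from .scoring import categorical_bonus

Z_975 = 1.959964  # standard normal 97.5% quantile

DEFAULT_PROBS = (0.025, 0.5, 0.975)


def implied_log_se(hr: HazardRatioEstimate) -> float:
    """Standard error of ln(HR) implied by a 95% confidence interval."""
    return math.log(hr.ci_high / hr.ci_low) / (2.0 * Z_975)


def sample_hr(hr: HazardRatioEstimate, n_draws: int, seed: int) -> np.ndarray:
    """Draw hazard ratios from the CI-implied log-normal; deterministic given seed.

    The distribution is centred at the geometric mean of the CI bounds so that
    its 2.5/97.5% quantiles reproduce the reported interval exactly.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    se = implied_log_se(hr)
    rng = np.random.default_rng(seed)
    if se == 0.0:  # degenerate interval: all draws equal the point
        return np.full(n_draws, hr.point)
    mu = 0.5 * (math.log(hr.ci_low) + math.log(hr.ci_high))
    return np.exp(rng.normal(mu, se, size=n_draws))


def _round_component_array(x: np.ndarray, decimals: int) -> np.ndarray:
    # vectorized truncation toward zero, with noise guards as in
    # scoring.round_component
    f = 10.0**decimals
    return np.trunc(np.round(x * f * 1e6) / 1e6) / f


class UncertaintySummary(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    n_draws: int
    seed: int
    nhb_quantiles: dict[float, float]
    cost_per_point_quantiles: dict[float, float]

    @model_validator(mode="after")
    def _monotone(self) -> "UncertaintySummary":
        for name, q in (("nhb", self.nhb_quantiles), ("cost_per_point", self.cost_per_point_quantiles)):
            probs = sorted(q)
            vals = [q[p] for p in probs]
            finite = [v for v in vals if not math.isnan(v)]
            if any(b < a for a, b in zip(finite, finite[1:])):
                raise ValueError(f"{name} quantiles must be non-decreasing in probability")
        return self


def nhb_interval(
    trial: TrialEvidence,
    dosing: RegimenDosing,
    config: Optional[ScoringConfig] = None,
    n_draws: int = 10_000,
    seed: int = 0,
    probs: Sequence[float] = DEFAULT_PROBS,
    toxicity_source: ToxicitySource = "reported",
) -> UncertaintySummary:
    """Propagate the death-HR confidence interval into NHB and cost-per-point quantiles.

    Toxicity and bonus points are held fixed at their scorecard values.
    Cost-per-point quantiles are computed over draws with positive NHB; draws
    with NHB <= 0 (where cost per point is undefined) propagate as NaN.
    """
    config = config or ScoringConfig()
    if trial.efficacy.death_hr is None:
        raise NoEfficacyEvidenceError("uncertainty propagation requires a death HR with CI")
    draws = sample_hr(trial.efficacy.death_hr, n_draws, seed)

    cb = _round_component_array(
        (1.0 - draws) * 100.0 * config.benefit_multipliers.os_hr, config.component_decimals
    )
    test_total = toxicity_points_total(trial.toxicity_test, config)
    comp_total = toxicity_points_total(trial.toxicity_comparator, config)
    if toxicity_source == "reported" and trial.reported_toxicity_score is not None:
        tox = trial.reported_toxicity_score
    else:
        tox = toxicity_score(test_total, comp_total, config)
    bonus_total = categorical_bonus(trial.bonus, config).total
    nhb = cb + tox + bonus_total

    cost = monthly_drug_cost(dosing, config)
    cpp = np.where(nhb > 0, cost / np.where(nhb > 0, nhb, np.nan), np.nan)

    probs = tuple(float(p) for p in probs)
    nhb_q = dict(zip(probs, np.quantile(nhb, probs)))
    cpp_q = dict(zip(probs, np.nanquantile(cpp, probs)))
    return UncertaintySummary(
        n_draws=n_draws, seed=seed, nhb_quantiles=nhb_q, cost_per_point_quantiles=cpp_q
    )
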