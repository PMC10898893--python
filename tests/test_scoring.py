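"""Steps 1-4: clinical benefit, toxicity, bonus points and NHB."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oncovalue as ov
from oncovalue.errors import UndefinedRatioError
from oncovalue.scoring import round_component


def _hr_efficacy(point, lo=None, hi=None):
    lo = lo if lo is not None else point * 0.8
    hi = hi if hi is not None else point * 1.2
    return ov.EfficacyEvidence(
        death_hr=ov.HazardRatioEstimate(
            point=point, ci_low=lo, ci_high=hi, endpoint="overall_survival"
        )
    )


class TestRounding:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((1 - 27 / 22) * 20, -4.54),  # truncation, not half-up rounding
            ((1 - 49.5 / 38) * 20, -6.05),
            ((1 - 44.5 / 40) * 20, -2.25),  # exact decimal survives
            ((1 - 49.5 / 45) * 20, -2.0),
            (2.259999, 2.25),
            (-2.2500000000004, -2.25),
        ],
    )
    def test_truncation_toward_zero(self, raw, expected):
        assert round_component(raw, 2) == expected


class TestClinicalBenefit:
    @pytest.mark.parametrize(
        "hr, expected", [(0.73, 27.0), (0.78, 22.0), (0.66, 34.0), (0.67, 33.0), (1.0, 0.0)]
    )
    def test_death_hr_rung(self, hr, expected, config):
        score = ov.clinical_benefit_score(_hr_efficacy(hr), config)
        assert score.points == expected
        assert score.rung == "1.A"

    def test_median_pfs_fallback(self, config):
        eff = ov.EfficacyEvidence(
            median_pfs=ov.MedianEstimate(
                median_test=12, median_comparator=10, endpoint="progression_free_survival"
            )
        )
        score = ov.clinical_benefit_score(eff, config)
        assert score.points == 16.0  # 100 * (12-10)/10 * 0.8
        assert score.rung == "1.D"

    def test_hierarchy_prefers_death_hr(self, config):
        eff = ov.EfficacyEvidence(
            death_hr=ov.HazardRatioEstimate(
                point=0.73, ci_low=0.61, ci_high=0.89, endpoint="overall_survival"
            ),
            median_pfs=ov.MedianEstimate(
                median_test=12, median_comparator=10, endpoint="progression_free_survival"
            ),
        )
        assert ov.clinical_benefit_score(eff, config).rung == "1.A"

    def test_harm_not_clamped(self, config):
        assert ov.clinical_benefit_score(_hr_efficacy(1.2), config).points < 0

    def test_monotone_decreasing_in_hr(self, config):
        grid = np.round(np.linspace(0.3, 1.3, 41), 3)
        scores = [ov.clinical_benefit_score(_hr_efficacy(h), config).points for h in grid]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestToxicity:
    @pytest.mark.parametrize(
        "band, freq, expected",
        [
            ("g1_2", 0.09, 0.5),
            ("g1_2", 0.10, 1.0),  # boundary takes the >= branch
            ("g1_2", 0.5, 1.0),
            ("g3_4", 0.03, 1.5),
            ("g3_4", 0.05, 2.0),  # boundary takes the >= branch
            ("g3_4", 0.07, 2.0),
        ],
    )
    def test_entry_points(self, band, freq, expected, config):
        assert ov.ae_entry_points(band, freq, config) == expected

    def test_entry_points_bad_frequency(self, config):
        with pytest.raises(ValueError):
            ov.ae_entry_points("g1_2", 1.2, config)

    def test_total_from_entries(self, config):
        profile = ov.ToxicityProfile(
            entries=[
                ov.AdverseEventEntry(term="a", grade_band="g1_2", frequency=0.12),
                ov.AdverseEventEntry(term="b", grade_band="g3_4", frequency=0.03),
                ov.AdverseEventEntry(term="c", grade_band="g3_4", frequency=0.06),
            ]
        )
        assert ov.toxicity_points_total(profile, config) == 4.5

    def test_empty_profile_scores_zero(self, config):
        assert ov.toxicity_points_total(ov.ToxicityProfile(), config) == 0.0

    def test_precomputed_total_wins(self, config):
        assert ov.toxicity_points_total(ov.ToxicityProfile(precomputed_total=49.5), config) == 49.5

    def test_itemized_total_matches_bruteforce_oracle(self, config):
        # independent per-entry point assignment over 1,000 random tables
        rng = np.random.default_rng(20230)
        for _ in range(1000):
            n = rng.integers(1, 25)
            bands = rng.choice(["g1_2", "g3_4"], size=n)
            freqs = rng.uniform(0, 1, size=n)
            profile = ov.ToxicityProfile(
                entries=[
                    ov.AdverseEventEntry(term=f"ae{i}", grade_band=b, frequency=float(f))
                    for i, (b, f) in enumerate(zip(bands, freqs))
                ]
            )
            expected = 0.0
            for b, f in zip(bands, freqs):
                if b == "g1_2":
                    expected += 0.5 if f < 0.10 else 1.0
                else:
                    expected += 1.5 if f < 0.05 else 2.0
            assert ov.toxicity_points_total(profile, config) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "test_total, comp_total, expected",
        [(49.5, 45, -2.0), (27, 22, -4.54), (49.5, 38, -6.05), (44.5, 40, -2.25), (7, 7, 0.0)],
    )
    def test_score_worked_values(self, test_total, comp_total, expected, config):
        assert ov.toxicity_score(test_total, comp_total, config) == expected

    @given(
        a=st.floats(min_value=0.1, max_value=100),
        b=st.floats(min_value=0.1, max_value=100),
    )
    def test_score_sign_tracks_toxicity_direction(self, a, b, config):
        score = ov.toxicity_score(a, b, config)
        if a < b:
            assert score > 0 or (score == 0 and (1 - a / b) * 20 < 0.01)
        elif a > b:
            assert score < 0 or (score == 0 and (a / b - 1) * 20 < 0.01)
        else:
            assert score == 0.0

    def test_score_undefined_for_nonpositive_comparator(self, config):
        with pytest.raises(UndefinedRatioError):
            ov.toxicity_score(10, 0, config)


class TestBonus:
    def test_absent_tail(self, config):
        verdict = ov.tail_of_curve_bonus(None, config)
        assert verdict.points == 0 and not verdict.eligible

    def test_awarded_points_when_eligible(self, config, spartan):
        verdict = ov.tail_of_curve_bonus(spartan.bonus.tail, config)
        assert verdict.eligible and verdict.points == 16

    def test_no_improvement(self, config):
        tail = ov.TailOfCurveEvidence(
            comparator_median=10, assessment_time=20, prop_test=0.3, prop_comparator=0.3
        )
        assert ov.tail_of_curve_bonus(tail, config).points == 0

    def test_comparator_floor(self, config):
        tail = ov.TailOfCurveEvidence(
            comparator_median=10, assessment_time=20, prop_test=0.30, prop_comparator=0.15
        )
        verdict = ov.tail_of_curve_bonus(tail, config)
        assert not verdict.eligible and "floor" in verdict.reason

    def test_default_magnitude_is_max(self, config):
        tail = ov.TailOfCurveEvidence(
            comparator_median=10, assessment_time=20, prop_test=0.45, prop_comparator=0.25
        )
        assert ov.tail_of_curve_bonus(tail, config).points == config.tail_max_points

    def test_prosper_breakdown(self, config, prosper):
        b = ov.categorical_bonus(prosper.bonus, config)
        assert (b.tail_points, b.palliation_points, b.qol_points, b.tfi_points) == (16, 0, 10, 0)
        assert b.total == 26

    def test_titan_breakdown(self, config, titan):
        assert ov.categorical_bonus(titan.bonus, config).total == 10

    def test_no_evidence_scores_zero(self, config):
        assert ov.categorical_bonus(ov.BonusEvidence(), config).total == 0


class TestNetHealthBenefit:
    @pytest.mark.parametrize(
        "cb, tox, bonus_total, expected",
        [(22, -4.54, 16, 33.46), (34, -2.0, 20, 52.0), (33, -2.25, 10, 40.75), (0, 0, 0, 0.0)],
    )
    def test_worked_values(self, cb, tox, bonus_total, expected, config):
        bonus = ov.BonusBreakdown(
            tail_points=bonus_total, palliation_points=0, qol_points=0, tfi_points=0, total=bonus_total
        )
        nhb = ov.net_health_benefit(cb, tox, bonus, config)
        assert nhb.nhb == pytest.approx(expected, abs=1e-12)
        assert nhb.max_possible == config.max_nhb

    @given(
        cb=st.floats(min_value=-100, max_value=100),
        tox=st.floats(min_value=-40, max_value=20),
        tail=st.floats(min_value=0, max_value=20),
        flags=st.tuples(st.booleans(), st.booleans(), st.booleans()),
    )
    def test_additivity(self, cb, tox, tail, flags, config):
        pall, qol, tfi = (10.0 if f else 0.0 for f in flags)
        bonus = ov.BonusBreakdown(
            tail_points=tail,
            palliation_points=pall,
            qol_points=qol,
            tfi_points=tfi,
            total=tail + pall + qol + tfi,
        )
        nhb = ov.net_health_benefit(cb, tox, bonus, config)
        assert nhb.nhb == cb + tox + bonus.total

    def test_nhb_monotone_decreasing_in_hr(self, config):
        # toxicity and bonus held fixed
        bonus = ov.categorical_bonus(ov.BonusEvidence(), config)
        grid = np.round(np.linspace(0.4, 1.1, 29), 3)
        nhbs = [
            ov.net_health_benefit(
                ov.clinical_benefit_score(_hr_efficacy(h), config).points, -2.0, bonus, config
            ).nhb
            for h in grid
        ]
        assert all(a > b for a, b in zip(nhbs, nhbs[1:]))
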