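"""Acute decision tree: branch probabilities, component costs, QALYs, end states."""

import math

import pytest
from hypothesis import given, strategies as st

from vhabpcea import branch_probabilities, derive_second_line, evaluate_acute
from vhabpcea.acute_tree import (
    DEAD,
    DISCHARGED,
    WARD,
    InfeasibleEfficacyError,
    acute_qaly,
    drug_cost,
    expected_ae_cost,
    ventilation_cost,
)
from vhabpcea.parameters import ArmEfficacy, RateWithBounds


def _eff(c1, m1, c2=0.5, m2=0.3, f=0.5):
    return ArmEfficacy(
        cure_first=RateWithBounds(value=c1),
        mort_first=RateWithBounds(value=m1),
        cure_second=RateWithBounds(value=c2),
        mort_second=RateWithBounds(value=m2),
        discharge_fraction_if_cured=f,
    )


class TestBranchProbabilities:
    @pytest.mark.parametrize(
        "c1,m1,expected_p2",
        [
            (0.606, 0.201, 0.193),  # CTZ/TAZ first line
            (0.571, 0.255, 0.174),  # MEPM first line
            (1.0, 0.0, 0.0),  # full cure
        ],
    )
    def test_second_line_entry_is_the_residual(self, c1, m1, expected_p2):
        probs = branch_probabilities(_eff(c1, m1))
        assert probs.p_to_second == pytest.approx(expected_p2)
        assert probs.p_cure1 + probs.p_die1 + probs.p_to_second == pytest.approx(1.0)

    def test_infeasible_rates_raise(self):
        eff = _eff(0.7, 0.2)
        eff.mort_first.value = 0.5  # bypasses the container-level check
        with pytest.raises(InfeasibleEfficacyError):
            branch_probabilities(eff)

    def test_conditional_mortality_mode(self):
        probs = branch_probabilities(_eff(0.6, 0.4), conditional_mortality=True)
        assert probs.p_die1 == pytest.approx(0.4 * 0.4)
        assert probs.p_to_second == pytest.approx(0.4 * 0.6)

    @given(
        c1=st.floats(0.0, 1.0),
        m1=st.floats(0.0, 1.0),
        c2=st.floats(0.0, 1.0),
        m2=st.floats(0.0, 1.0),
        f=st.floats(0.0, 1.0),
    )
    def test_branches_always_sum_to_one(self, c1, m1, c2, m2, f):
        if c1 + m1 > 1.0 or c2 + m2 > 1.0:
            return
        p = branch_probabilities(_eff(c1, m1, c2, m2, f))
        assert p.p_cure1 + p.p_die1 + p.p_to_second == pytest.approx(1.0, abs=1e-12)
        assert p.p_cure2 + p.p_die2 + p.p_longterm_icu == pytest.approx(1.0, abs=1e-12)
        assert p.p_discharge_given_cure + p.p_ward_given_cure == pytest.approx(1.0)


class TestSecondLineDerivation:
    @pytest.mark.parametrize(
        "m1,expected_m2",
        [(0.201, 0.2412), (0.255, 0.306), (0.0, 0.0)],
    )
    def test_mortality_penalty(self, m1, expected_m2):
        _, m2 = derive_second_line(0.6, m1, 0.10, 0.20)
        assert m2 == pytest.approx(expected_m2)

    def test_cure_penalty(self):
        c2, _ = derive_second_line(0.606, 0.2, 0.10, 0.20)
        assert c2 == pytest.approx(0.606 * 0.9)

    def test_out_of_range_result_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            _, m2 = derive_second_line(0.0, 0.9, 0.1, 0.5)
        assert m2 == 1.0


class TestCostComponents:
    """Closed-form arithmetic on the published unit costs."""

    @pytest.mark.parametrize(
        "daily,days,expected",
        [
            (36_414.0, 8.0, 291_312.0),
            (2_589.0, 8.23, 21_307.47),
            (36_414.0 + 714.0, 7.0, 259_896.0),
            (2_589.0 + 714.0, 7.0, 23_121.0),
        ],
    )
    def test_drug_course_cost(self, daily, days, expected):
        assert drug_cost(daily, days) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "days,phase,expected",
        [(12, "first", 114_000.0), (13, "first", 123_500.0), (12, "second", 97_800.0)],
    )
    def test_two_tier_ventilation_tariff(self, days, phase, expected):
        assert ventilation_cost(
            days, phase, early_daily=9_500.0, late_daily=8_150.0
        ) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "rates,amk,expected",
        [
            ({"ss": 0.036, "mo": 0.039, "cf": 0.025}, False, 42_435.33),
            ({"ss": 0.047, "mo": 0.028, "cf": 0.022}, False, 41_887.05),
            ({"ss": 0.036, "mo": 0.039, "cf": 0.025}, True, 48_123.33),
            ({"ss": 0.047, "mo": 0.028, "cf": 0.022}, True, 47_575.05),
            ({"ss": 0.0, "mo": 0.0, "cf": 0.0}, False, 0.0),
        ],
    )
    def test_expected_ae_cost(self, rates, amk, expected):
        costs = {"ss": 504_885.0, "mo": 504_885.0, "cf": 182_758.0}
        got = expected_ae_cost(
            rates, costs, include_amk=amk, amk_rate=0.06, amk_cost=94_800.0
        )
        assert got == pytest.approx(expected, abs=0.006)

    def test_missing_ae_cost_raises(self):
        with pytest.raises(KeyError, match="no cost"):
            expected_ae_cost({"x": 0.1}, {})

    @given(
        scale=st.floats(0.0, 1.0),
        r1=st.floats(0.0, 1.0),
        r2=st.floats(0.0, 1.0),
        c1=st.floats(0.0, 1e6),
        c2=st.floats(0.0, 1e6),
    )
    def test_ae_cost_linear_in_rates_and_costs(self, scale, r1, r2, c1, c2):
        costs = {"a": c1, "b": c2}
        base = expected_ae_cost({"a": r1, "b": r2}, costs)
        scaled = expected_ae_cost({"a": scale * r1, "b": scale * r2}, costs)
        assert scaled == pytest.approx(scale * base, rel=1e-12, abs=1e-9)
        # superposition across the two AEs
        only_a = expected_ae_cost({"a": r1}, costs)
        only_b = expected_ae_cost({"b": r2}, costs)
        assert only_a + only_b == pytest.approx(base, rel=1e-12, abs=1e-9)


class TestAcuteQaly:
    def test_single_branch_icu_stay(self, params):
        dur = params.durations["ctz_taz"]
        probs = branch_probabilities(_eff(1.0, 0.0))  # nobody reaches second line
        q = acute_qaly(dur, probs, params.utilities)
        assert q == pytest.approx(-0.39 * 28 / 365.25)
        assert q == pytest.approx(-0.029897330595482545)

    def test_zero_icu_utility_gives_zero(self, params):
        params.utilities.icu_vent.value = 0.0
        probs = branch_probabilities(_eff(0.6, 0.2))
        q = acute_qaly(params.durations["ctz_taz"], probs, params.utilities)
        assert q == 0.0


class TestEvaluateAcute:
    def test_fixture_breakdown_matches_published_components(self, base_params):
        out = evaluate_acute("ctz_taz", base_params)
        b = out.cost_breakdown
        assert b.drug_first == pytest.approx(291_312.0)
        assert b.drug_second == pytest.approx(259_896.0)
        assert b.ventilation_first == pytest.approx(114_000.0)
        assert b.ae_second == pytest.approx(48_123.33, abs=0.006)
        assert b.hospitalization_first == pytest.approx(2_136_960.0)

    def test_end_states_sum_to_one(self, base_params):
        for arm in ("ctz_taz", "mepm"):
            out = evaluate_acute(arm, base_params)
            total = sum(s.probability for s in out.end_states)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_full_cure_path(self, params):
        eff = params.efficacy["ctz_taz"]
        params.efficacy["ctz_taz"] = type(eff)(
            cure_first=RateWithBounds(value=1.0),
            mort_first=RateWithBounds(value=0.0),
            cure_second=eff.cure_second,
            mort_second=eff.mort_second,
            discharge_fraction_if_cured=1.0,
        )
        out = evaluate_acute("ctz_taz", params)
        assert out.end_state_distribution() == pytest.approx(
            {DISCHARGED: 1.0, WARD: 0.0, DEAD: 0.0}
        )
        b = out.cost_breakdown
        first_line_only = (
            b.drug_first + b.hospitalization_first + b.ventilation_first + b.ae_first
        )
        assert out.expected_cost == pytest.approx(first_line_only)

    def test_path_enumeration_oracle(self, base_params):
        """Brute-force root-to-leaf enumeration reproduces the expected cost."""
        for arm in ("ctz_taz", "mepm"):
            out = evaluate_acute(arm, base_params)
            eff = base_params.efficacy[arm]
            c = base_params.costs
            daily = c.drug_daily_ctz_taz if arm == "ctz_taz" else c.drug_daily_mepm
            d = base_params.durations[arm]
            first = (
                daily * d.admin_days_first.value
                + c.hospitalization_first[arm]
                + 9_500.0 * d.vent_days_first.value
                + sum(
                    r.value * c.ae_costs[n].value
                    for n, r in base_params.ae.by_arm[arm].items()
                )
            )
            second = (
                (daily + c.drug_daily_amk) * d.admin_days_second.value
                + c.hospitalization_second[arm]
                + 8_150.0 * d.vent_days_second.value
                + sum(
                    r.value * c.ae_costs[n].value
                    for n, r in base_params.ae.by_arm[arm].items()
                )
                + base_params.ae.amk.value * c.ae_costs["acute_renal_failure"].value
            )
            c1, m1 = eff.cure_first.value, eff.mort_first.value
            c2, m2 = eff.cure_second.value, eff.mort_second.value
            p2 = 1.0 - c1 - m1
            plt = 1.0 - c2 - m2
            f = eff.discharge_fraction_if_cured
            ward, lt = c.long_term_ward, c.long_term_icu
            paths = [
                (c1 * f, first),
                (c1 * (1 - f), first + ward),
                (m1, first),
                (p2 * c2 * f, first + second),
                (p2 * c2 * (1 - f), first + second + ward),
                (p2 * m2, first + second),
                (p2 * plt, first + second + lt),
            ]
            assert sum(p for p, _ in paths) == pytest.approx(1.0, abs=1e-12)
            oracle = sum(p * cost for p, cost in paths)
            assert out.expected_cost == pytest.approx(oracle, rel=1e-9)

    def test_cost_monotone_in_inputs(self, params, base_params):
        base = evaluate_acute("ctz_taz", base_params).expected_cost
        params.durations["ctz_taz"].vent_days_first.value += 5.0
        more_vent = evaluate_acute("ctz_taz", params).expected_cost
        assert more_vent > base
        params.costs.drug_daily_ctz_taz += 1_000.0
        more_drug = evaluate_acute("ctz_taz", params).expected_cost
        assert more_drug > more_vent

    def test_derived_second_line_mode(self, params):
        params.settings.derive_second_line = True
        out = evaluate_acute("mepm", params)
        assert out.probabilities.p_die2 == pytest.approx(0.306)
        assert out.probabilities.p_cure2 == pytest.approx(0.571 * 0.9)
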