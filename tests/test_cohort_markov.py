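"""Markov cohort engine: discounting, cycle conversion, traces and oracles."""

import numpy as np
import pytest

from vhabpcea import annual_to_cycle_probability, discount_factor, run_cohort
from vhabpcea.acute_tree import DEAD, DISCHARGED, WARD, EndStateSlice
from vhabpcea.cohort_markov import MarkovSpec, markov_spec_from


def flat_table(q, ages=range(0, 120)):
    return {a: q for a in ages}


def make_spec(**kw):
    defaults = dict(
        life_table=flat_table(0.02),
        cycle_length_days=30.0,
        horizon_days=1800.0,
        discount_rate_annual=0.02,
        ward_mortality_per_stay=0.076,
        start_age=65.0,
        u_discharged=0.8,
        u_ward=0.77,
    )
    defaults.update(kw)
    return MarkovSpec(**defaults)


class TestDiscounting:
    @pytest.mark.parametrize(
        "years,rate,expected",
        [
            (3.7, 0.0, 1.0),
            (1.0, 0.02, 0.9803921568627451),
            (5.0, 0.02, 0.9057308098299158),
        ],
    )
    def test_discount_factor(self, years, rate, expected):
        assert discount_factor(years, rate) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "p,days,expected",
        [
            (0.0, 30.0, 0.0),
            (1.0, 30.0, 1.0),
            (0.02, 30.0, 0.0016579839674176755),
        ],
    )
    def test_annual_to_cycle(self, p, days, expected):
        assert annual_to_cycle_probability(p, days) == pytest.approx(expected, rel=1e-12)


class TestRunCohort:
    def test_all_dead_accrues_nothing(self):
        trace = run_cohort({DEAD: 1.0}, make_spec())
        assert trace.total_qaly == 0.0
        assert trace.total_cost == 0.0

    def test_no_mortality_no_discount_closed_form(self):
        # 0.8 utility over exactly 5 years of life
        spec = make_spec(
            life_table=flat_table(0.0),
            discount_rate_annual=0.0,
            horizon_days=5 * 365.25,
        )
        trace = run_cohort({DISCHARGED: 1.0}, spec)
        assert trace.total_qaly == pytest.approx(0.8 * 5.0, rel=1e-12)

    def test_constant_hazard_closed_form_oracle(self):
        """Engine total equals the independent geometric-series summation."""
        spec = make_spec()  # q = 2 %/yr, r = 2 %, 60 full cycles
        trace = run_cohort({DISCHARGED: 1.0}, spec)
        s = 0.98 ** (30 / 365.25)
        t = np.arange(60)
        oracle = np.sum(
            0.8 * (30 / 365.25) * s**t * 1.02 ** (-(30 * t + 15) / 365.25)
        )
        assert oracle == pytest.approx(3.581167287124634, rel=1e-12)  # frozen
        assert trace.total_qaly == pytest.approx(oracle, rel=1e-12)

    def test_unnormalized_initial_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            run_cohort({DISCHARGED: 0.6}, make_spec())

    def test_occupancy_conservation(self):
        spec = make_spec()
        init = {DISCHARGED: 0.55, WARD: 0.35, DEAD: 0.10}
        trace = run_cohort(init, spec)
        grouped = trace.records.groupby("cycle")[["occupancy", "dead"]].sum()
        total = grouped["occupancy"] + grouped["dead"] + 0.10
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_ward_lasts_one_cycle_then_discharged(self):
        spec = make_spec(life_table=flat_table(0.0), discount_rate_annual=0.0)
        trace = run_cohort({WARD: 1.0}, spec)
        states = trace.records.sort_values("cycle")["state"].tolist()
        assert states[0] == WARD
        assert all(s == DISCHARGED for s in states[1:])
        # survivors of the single ward month
        occ_after = trace.records.sort_values("cycle")["occupancy"].iloc[1]
        assert occ_after == pytest.approx(1.0 - 0.076)

    def test_discounting_reduces_totals(self):
        undisc = run_cohort({DISCHARGED: 1.0}, make_spec(discount_rate_annual=0.0))
        disc = run_cohort({DISCHARGED: 1.0}, make_spec(discount_rate_annual=0.02))
        assert disc.total_qaly < undisc.total_qaly

    @pytest.mark.parametrize("factor", [2.0, 5.0])
    def test_qalys_decrease_with_background_mortality(self, factor):
        lo = run_cohort({DISCHARGED: 1.0}, make_spec(life_table=flat_table(0.01)))
        hi = run_cohort(
            {DISCHARGED: 1.0}, make_spec(life_table=flat_table(0.01 * factor))
        )
        assert hi.total_qaly < lo.total_qaly

    def test_offsets_shorten_the_accrual_window(self):
        spec = make_spec(life_table=flat_table(0.0), discount_rate_annual=0.0,
                         horizon_days=365.25)
        full = run_cohort([EndStateSlice(DISCHARGED, 1.0, 0.0)], spec)
        late = run_cohort([EndStateSlice(DISCHARGED, 1.0, 182.625)], spec)
        assert late.total_qaly == pytest.approx(full.total_qaly / 2.0, rel=1e-9)

    def test_age_advances_with_elapsed_time(self):
        # steeply rising table: an older cohort must lose more people
        table = {a: min(0.001 * 1.5 ** max(a - 65, 0), 0.9) for a in range(0, 120)}
        young = run_cohort({DISCHARGED: 1.0}, make_spec(life_table=table, start_age=65))
        old = run_cohort({DISCHARGED: 1.0}, make_spec(life_table=table, start_age=75))
        assert old.total_qaly < young.total_qaly


class TestMicrosimulationOracle:
    def test_cohort_equals_individual_simulation(self):
        """10^5 simulated patients with the same hazards agree within MC error."""
        spec = make_spec(life_table=flat_table(0.015), horizon_days=1800.0)
        trace = run_cohort({DISCHARGED: 1.0}, spec)

        rng = np.random.default_rng(20240328)
        n = 100_000
        n_cycles = 60
        q_cycle = annual_to_cycle_probability(0.015, 30.0)
        alive = np.ones(n, dtype=bool)
        qalys = np.zeros(n)
        for t in range(n_cycles):
            df = 1.02 ** (-(30 * t + 15) / 365.25)
            qalys[alive] += 0.8 * (30 / 365.25) * df
            alive &= rng.random(n) >= q_cycle
        mc_mean = qalys.mean()
        mc_se = qalys.std(ddof=1) / np.sqrt(n)
        assert trace.total_qaly == pytest.approx(mc_mean, abs=3.5 * mc_se)


def test_spec_from_parameters(base_params):
    spec = markov_spec_from(base_params)
    assert spec.horizon_days == pytest.approx(5 * 365.25)
    assert spec.u_discharged == 0.8
    assert spec.ward_mortality_per_stay == 0.076
    assert spec.annual_death_probability(65.7) == base_params.life_table[65]
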