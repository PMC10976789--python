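"""Acute-phase decision tree for one treatment arm.

Patients enter on first-line therapy in the ICU (ventilated).  Each
line ends in "cured" or "not cured"; uncured first-line patients either
die or move to second-line therapy (first-line drug plus amikacin, with
21 additional ICU days).  Uncured second-line patients either die or
spend a terminal month in long-term ICU care and then die.  Cured
patients are discharged home or spend one month on a general ward.

This module computes, per arm: the branch probabilities, the
component-wise costs (drug, hospitalization, ventilation, AE treatment,
long-term care), the expected acute cost under branch occupancy, the
acute-phase QALY contribution (ICU time at a negative utility), and the
distribution over end states -- with elapsed-time offsets -- handed to
the long-term Markov engine.

Cost convention: components are stored *unweighted* (the full cost of a
line, as a published breakdown table would print them); the expectation
weights each component by the probability of incurring it.  Costs of a
treatment line are incurred by every patient entering it, cured or not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

from .parameters import (
    ArmDurations,
    ArmEfficacy,
    Arm,
    ParameterSet,
    UtilityInputs,
)

__all__ = [
    "DISCHARGED",
    "WARD",
    "DEAD",
    "STATES",
    "BranchProbabilities",
    "AcuteCostBreakdown",
    "EndStateSlice",
    "ArmAcuteOutcome",
    "branch_probabilities",
    "derive_second_line",
    "drug_cost",
    "ventilation_cost",
    "expected_ae_cost",
    "acute_qaly",
    "evaluate_acute",
    "breakdown_frame",
]

State = Literal["DischargedAlive", "InWard", "Dead"]
DISCHARGED: State = "DischargedAlive"
WARD: State = "InWard"
DEAD: State = "Dead"
STATES: tuple[State, ...] = (DISCHARGED, WARD, DEAD)


class InfeasibleEfficacyError(ValueError):
    """Cure + mortality on one treatment line exceeds 1."""


@dataclass(frozen=True)
class BranchProbabilities:
    """All branch probabilities of the acute tree for one arm.

    First-line probabilities are unconditional; second-line
    probabilities are conditional on entering second-line treatment.
    """

    p_cure1: float
    p_die1: float
    p_to_second: float
    p_cure2: float
    p_die2: float
    p_longterm_icu: float
    p_discharge_given_cure: float
    p_ward_given_cure: float

    @property
    def p_cure_total(self) -> float:
        """Unconditional probability of cure on either line."""
        return self.p_cure1 + self.p_to_second * self.p_cure2


def branch_probabilities(
    eff: ArmEfficacy, *, conditional_mortality: bool = False
) -> BranchProbabilities:
    """Turn cure/mortality rates into a complete branch-probability set.

    By default the published mortality is read as marginal over all
    patients entering the line (all-cause trial reporting), so the
    second-line / long-term-ICU branch receives the residual
    ``1 - cure - mortality``.  With ``conditional_mortality=True`` the
    mortality applies to the uncured fraction instead.
    """
    c1, m1 = eff.cure_first.value, eff.mort_first.value
    c2, m2 = eff.cure_second.value, eff.mort_second.value
    if conditional_mortality:
        die1 = (1.0 - c1) * m1
        die2 = (1.0 - c2) * m2
    else:
        die1, die2 = m1, m2
    rest1 = 1.0 - c1 - die1
    rest2 = 1.0 - c2 - die2
    if rest1 < -1e-12 or rest2 < -1e-12:
        raise InfeasibleEfficacyError(
            f"cure + mortality exceeds 1 (first line residual {rest1:.4g}, "
            f"second line residual {rest2:.4g})"
        )
    f = eff.discharge_fraction_if_cured
    return BranchProbabilities(
        p_cure1=c1,
        p_die1=die1,
        p_to_second=max(rest1, 0.0),
        p_cure2=c2,
        p_die2=die2,
        p_longterm_icu=max(rest2, 0.0),
        p_discharge_given_cure=f,
        p_ward_given_cure=1.0 - f,
    )


def derive_second_line(
    cure_first: float,
    mort_first: float,
    cure_reduction: float,
    mort_increase: float,
) -> tuple[float, float]:
    """Second-line rates from first-line rates under the failure penalty.

    Cure is reduced by ``cure_reduction`` (relative) and mortality
    increased by ``mort_increase`` (relative), reflecting the extra
    burden of having failed first-line therapy.  Results outside [0, 1]
    are clamped with a warning.
    """
    cure2 = cure_first * (1.0 - cure_reduction)
    mort2 = mort_first * (1.0 + mort_increase)
    for name, v in (("cure", cure2), ("mortality", mort2)):
        if not (0.0 <= v <= 1.0):
            warnings.warn(f"derived second-line {name} {v:.4g} clamped to [0, 1]")
    cure2 = min(max(cure2, 0.0), 1.0)
    mort2 = min(max(mort2, 0.0), 1.0)
    return cure2, mort2


def drug_cost(daily_cost: float, duration_days: float) -> float:
    """Cost of a drug course: daily price x administration days."""
    if daily_cost < 0 or duration_days < 0:
        raise ValueError("daily cost and duration must be non-negative")
    return daily_cost * duration_days


def ventilation_cost(
    days: float,
    phase: Literal["first", "second"],
    *,
    early_daily: float,
    late_daily: float,
) -> float:
    """Mechanical-ventilation cost under the two-tier daily tariff.

    The fee schedule pays a higher daily rate through day 14 and a lower
    one from day 15.  First-line ventilation (always started at day 0,
    within the early window) is billed at the early tariff; second-line
    ventilation, which cumulatively falls past day 14, at the late one.
    """
    if days < 0:
        raise ValueError("ventilation days must be non-negative")
    rate = early_daily if phase == "first" else late_daily
    return days * rate


def expected_ae_cost(
    ae_rates: Mapping[str, float],
    ae_costs: Mapping[str, float],
    *,
    include_amk: bool = False,
    amk_rate: float = 0.0,
    amk_cost: float = 0.0,
) -> float:
    """Expected adverse-event treatment cost: sum of incidence x per-event cost.

    Second-line courses add the aminoglycoside nephrotoxicity term via
    ``include_amk``.
    """
    total = 0.0
    for name, rate in ae_rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"AE rate for {name} outside [0, 1]: {rate}")
        if name not in ae_costs:
            raise KeyError(f"AE {name!r} has an incidence but no cost")
        total += rate * ae_costs[name]
    if include_amk:
        total += amk_rate * amk_cost
    return total


@dataclass(frozen=True)
class AcuteCostBreakdown:
    """Unweighted per-component costs (yen) mirroring the published breakdown."""

    drug_first: float
    drug_second: float
    hospitalization_first: float
    hospitalization_second: float
    ventilation_first: float
    ventilation_second: float
    ae_first: float
    ae_second: float
    long_term_icu: float
    long_term_ward: float

    def as_dict(self) -> dict[str, float]:
        return {
            "drug_first": self.drug_first,
            "drug_second": self.drug_second,
            "hospitalization_first": self.hospitalization_first,
            "hospitalization_second": self.hospitalization_second,
            "ventilation_first": self.ventilation_first,
            "ventilation_second": self.ventilation_second,
            "ae_first": self.ae_first,
            "ae_second": self.ae_second,
            "long_term_icu": self.long_term_icu,
            "long_term_ward": self.long_term_ward,
        }

    def component_weights(self, probs: BranchProbabilities) -> dict[str, float]:
        """Probability of incurring each component (branch occupancy)."""
        p2 = probs.p_to_second
        return {
            "drug_first": 1.0,
            "drug_second": p2,
            "hospitalization_first": 1.0,
            "hospitalization_second": p2,
            "ventilation_first": 1.0,
            "ventilation_second": p2,
            "ae_first": 1.0,
            "ae_second": p2,
            "long_term_icu": p2 * probs.p_longterm_icu,
            "long_term_ward": probs.p_cure_total * probs.p_ward_given_cure,
        }

    def expected_total(self, probs: BranchProbabilities) -> float:
        w = self.component_weights(probs)
        c = self.as_dict()
        return sum(w[k] * c[k] for k in c)


@dataclass(frozen=True)
class EndStateSlice:
    """A cohort fraction leaving the acute phase in ``state`` at ``offset_days``."""

    state: State
    probability: float
    offset_days: float


@dataclass(frozen=True)
class ArmAcuteOutcome:
    arm: Arm
    probabilities: BranchProbabilities
    cost_breakdown: AcuteCostBreakdown
    expected_cost: float
    acute_qaly: float
    end_states: tuple[EndStateSlice, ...] = field(default_factory=tuple)

    def end_state_distribution(self) -> dict[State, float]:
        out: dict[State, float] = {s: 0.0 for s in STATES}
        for sl in self.end_states:
            out[sl.state] += sl.probability
        return out


def acute_qaly(
    durations: ArmDurations,
    probs: BranchProbabilities,
    utilities: UtilityInputs,
    *,
    days_per_year: float = 365.25,
    days_per_month: float = 30.0,
) -> float:
    """Acute-phase QALY contribution (ICU time only, undiscounted).

    Every patient accrues the first-line ICU stay at the ventilated-ICU
    utility; second-line entrants accrue the additional ICU days; the
    long-term-ICU branch accrues the terminal month.  The ward month of
    cured patients is accrued by the Markov engine, not here.  The
    result is typically negative because the ventilated-ICU utility is
    below zero (a state judged worse than death).
    """
    u = utilities.icu_vent.value
    days = durations.icu_los_first.value
    days += probs.p_to_second * durations.icu_los_second_additional.value
    days += (
        probs.p_to_second
        * probs.p_longterm_icu
        * durations.terminal_icu_months
        * days_per_month
    )
    return u * days / days_per_year


def evaluate_acute(arm: Arm, params: ParameterSet) -> ArmAcuteOutcome:
    """Evaluate the full acute tree for one arm of a validated ParameterSet."""
    eff = params.efficacy[arm]
    if params.settings.derive_second_line:
        c2, m2 = derive_second_line(
            eff.cure_first.value,
            eff.mort_first.value,
            params.settings.second_line_cure_reduction,
            params.settings.second_line_mort_increase,
        )
        eff = eff.model_copy(deep=True)
        eff.cure_second.value = c2
        eff.mort_second.value = m2
    probs = branch_probabilities(
        eff, conditional_mortality=params.settings.mortality_conditional_on_noncure
    )
    dur = params.durations[arm]
    costs = params.costs
    daily_first = (
        costs.drug_daily_ctz_taz if arm == "ctz_taz" else costs.drug_daily_mepm
    )
    ae_rates = {name: r.value for name, r in params.ae.by_arm[arm].items()}
    ae_costs = {name: c.value for name, c in costs.ae_costs.items()}
    amk_cost = ae_costs.get(params.ae.amk_name, 0.0)

    breakdown = AcuteCostBreakdown(
        drug_first=drug_cost(daily_first, dur.admin_days_first.value),
        drug_second=drug_cost(
            daily_first + costs.drug_daily_amk, dur.admin_days_second.value
        ),
        hospitalization_first=costs.hospitalization_first[arm],
        hospitalization_second=costs.hospitalization_second[arm],
        ventilation_first=ventilation_cost(
            dur.vent_days_first.value,
            "first",
            early_daily=costs.vent_daily_early,
            late_daily=costs.vent_daily_late,
        ),
        ventilation_second=ventilation_cost(
            dur.vent_days_second.value,
            "second",
            early_daily=costs.vent_daily_early,
            late_daily=costs.vent_daily_late,
        ),
        ae_first=expected_ae_cost(ae_rates, ae_costs),
        ae_second=expected_ae_cost(
            ae_rates,
            ae_costs,
            include_amk=True,
            amk_rate=params.ae.amk.value,
            amk_cost=amk_cost,
        ),
        long_term_icu=costs.long_term_icu,
        long_term_ward=costs.long_term_ward,
    )

    month = params.settings.cycle_length_days  # the model's "one month"
    t1 = dur.icu_los_first.value
    t2 = t1 + dur.icu_los_second_additional.value
    t_term = t2 + dur.terminal_icu_months * month
    p2 = probs.p_to_second
    f = probs.p_discharge_given_cure
    slices = [
        EndStateSlice(DISCHARGED, probs.p_cure1 * f, t1),
        EndStateSlice(WARD, probs.p_cure1 * (1.0 - f), t1),
        EndStateSlice(DEAD, probs.p_die1, t1),
        EndStateSlice(DISCHARGED, p2 * probs.p_cure2 * f, t2),
        EndStateSlice(WARD, p2 * probs.p_cure2 * (1.0 - f), t2),
        EndStateSlice(DEAD, p2 * probs.p_die2, t2),
        EndStateSlice(DEAD, p2 * probs.p_longterm_icu, t_term),
    ]
    slices = tuple(s for s in slices if s.probability > 0.0)

    return ArmAcuteOutcome(
        arm=arm,
        probabilities=probs,
        cost_breakdown=breakdown,
        expected_cost=breakdown.expected_total(probs),
        acute_qaly=acute_qaly(
            dur,
            probs,
            params.utilities,
            days_per_year=params.settings.days_per_year,
            days_per_month=month,
        ),
        end_states=slices,
    )


def breakdown_frame(outcomes: Mapping[Arm, ArmAcuteOutcome]) -> pd.DataFrame:
    """Tidy per-component cost table (one row per component, one column per arm).

    Columns: ``component``, then per arm the unweighted cost, the
    occupancy weight and the expected (weighted) cost.
    """
    rows = []
    first = outcomes[next(iter(outcomes))]
    for comp in first.cost_breakdown.as_dict():
        row: dict[str, object] = {"component": comp}
        for arm, out in outcomes.items():
            c = out.cost_breakdown.as_dict()[comp]
            w = out.cost_breakdown.component_weights(out.probabilities)[comp]
            row[f"{arm}_cost"] = c
            row[f"{arm}_weight"] = w
            row[f"{arm}_expected"] = c * w
        rows.append(row)
    return pd.DataFrame(rows)
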