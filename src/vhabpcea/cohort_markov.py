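"""Long-term Markov cohort engine over {DischargedAlive, InWard, Dead}.

The cohort leaving the acute tree is a set of slices (state, probability,
time offset from treatment start).  Each slice is propagated in
discrete cycles (30 days by default) until the model horizon, measured
from treatment start, is reached; the final cycle is truncated to the
horizon.

Dynamics per cycle:

* ``InWard`` lasts exactly one cycle: the ward (in-hospital) mortality
  is applied once during it and survivors move to ``DischargedAlive``.
* ``DischargedAlive`` is subject to age-dependent background mortality
  from the life table, converted from an annual to a per-cycle
  probability; age advances with elapsed time (integer-age lookup).
* ``Dead`` is absorbing and accrues nothing.

QALYs accrue as start-of-cycle occupancy x state utility x cycle length
in years, discounted at the cycle midpoint.  State costs default to
zero (no post-discharge costs are modelled; ward and ICU care costs are
charged in the acute tree).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .acute_tree import DEAD, DISCHARGED, STATES, WARD, EndStateSlice, State
from .parameters import ParameterSet

__all__ = [
    "MarkovSpec",
    "CohortTrace",
    "discount_factor",
    "annual_to_cycle_probability",
    "run_cohort",
    "markov_spec_from",
]


def discount_factor(elapsed_years: float, rate: float) -> float:
    """Present-value factor 1/(1+r)^t, continuous in elapsed time."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + rate) ** (-elapsed_years)


def annual_to_cycle_probability(
    p_annual: float, cycle_days: float, days_per_year: float = 365.25
) -> float:
    """Convert an annual event probability to a per-cycle probability.

    Assumes a constant hazard within the year:
    ``1 - (1 - p)^(cycle_days / days_per_year)``.
    """
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"annual probability outside [0, 1]: {p_annual}")
    return 1.0 - (1.0 - p_annual) ** (cycle_days / days_per_year)


@dataclass(frozen=True)
class MarkovSpec:
    """Everything the cohort engine needs, decoupled from ParameterSet."""

    life_table: Mapping[int, float]
    cycle_length_days: float = 30.0
    horizon_days: float = 5 * 365.25
    discount_rate_annual: float = 0.02
    ward_mortality_per_stay: float = 0.076
    start_age: float = 65.0
    u_discharged: float = 0.8
    u_ward: float = 0.77
    state_costs_per_cycle: Mapping[str, float] = field(default_factory=dict)
    days_per_year: float = 365.25

    def annual_death_probability(self, age: float) -> float:
        a = int(math.floor(age))
        if a in self.life_table:
            return self.life_table[a]
        return self.life_table[max(self.life_table)]


def markov_spec_from(params: ParameterSet) -> MarkovSpec:
    s = params.settings
    return MarkovSpec(
        life_table=params.life_table,
        cycle_length_days=s.cycle_length_days,
        horizon_days=s.horizon_years * s.days_per_year,
        discount_rate_annual=s.discount_rate_annual,
        ward_mortality_per_stay=s.ward_mortality,
        start_age=s.cohort_start_age,
        u_discharged=params.utilities.discharged.value,
        u_ward=params.utilities.ward.value,
        days_per_year=s.days_per_year,
    )


@dataclass
class CohortTrace:
    """Per-cycle records plus cumulative discounted totals for one cohort."""

    records: pd.DataFrame
    total_qaly: float
    total_cost: float

    def occupancy_by_cycle(self) -> pd.DataFrame:
        """Aggregate state occupancy per cycle index (for conservation checks)."""
        if self.records.empty:
            return pd.DataFrame(columns=["cycle", *STATES])
        piv = self.records.pivot_table(
            index="cycle", columns="state", values="occupancy", aggfunc="sum"
        )
        for s in STATES:
            if s not in piv.columns:
                piv[s] = 0.0
        return piv[list(STATES)].fillna(0.0).reset_index()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _normalize_initial(
    initial: Sequence[EndStateSlice] | Mapping[State, float],
) -> list[EndStateSlice]:
    if isinstance(initial, Mapping):
        slices = [EndStateSlice(s, p, 0.0) for s, p in initial.items()]
    else:
        slices = list(initial)
    for sl in slices:
        if sl.state not in STATES:
            raise ValueError(f"unknown state {sl.state!r}")
        if sl.probability < 0:
            raise ValueError("negative slice probability")
    total = sum(sl.probability for sl in slices)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"initial distribution sums to {total!r}, expected 1")
    return slices


def run_cohort(
    initial: Sequence[EndStateSlice] | Mapping[State, float], spec: MarkovSpec
) -> CohortTrace:
    """Propagate the post-acute cohort to the horizon and accumulate payoffs.

    ``initial`` is either a mapping state -> probability (all starting
    at time 0) or a sequence of :class:`EndStateSlice` with individual
    time offsets.  Must sum to 1.  Returns a :class:`CohortTrace`
    whose ``records`` hold one row per slice per cycle per state with
    start-of-cycle occupancy and the discounted QALY/cost increments.
    """
    slices = _normalize_initial(initial)
    rows: list[dict] = []
    total_qaly = 0.0
    total_cost = 0.0
    dpy = spec.days_per_year
    r = spec.discount_rate_annual

    for idx, sl in enumerate(slices):
        occ = sl.probability
        dead = 0.0
        if sl.state == DEAD or occ == 0.0:
            continue
        in_ward = sl.state == WARD
        t = sl.offset_days
        cycle = 0
        while t < spec.horizon_days - 1e-9:
            t_end = min(t + spec.cycle_length_days, spec.horizon_days)
            frac_years = (t_end - t) / dpy
            df = discount_factor(((t + t_end) / 2.0) / dpy, r)
            state = WARD if in_ward else DISCHARGED
            u = spec.u_ward if in_ward else spec.u_discharged
            dq = occ * u * frac_years * df
            cost_rate = spec.state_costs_per_cycle.get(state, 0.0)
            dc = occ * cost_rate * ((t_end - t) / spec.cycle_length_days) * df
            rows.append(
                {
                    "slice": idx,
                    "cycle": cycle,
                    "state": state,
                    "t_start_days": t,
                    "t_end_days": t_end,
                    "occupancy": occ,
                    "dead": dead,
                    "dqaly": dq,
                    "dcost": dc,
                }
            )
            total_qaly += dq
            total_cost += dc
            if in_ward:
                # one-month ward stay: apply the per-stay mortality once
                died = occ * spec.ward_mortality_per_stay
                occ -= died
                dead += died
                in_ward = False
            else:
                age = spec.start_age + t / dpy
                q_cycle = annual_to_cycle_probability(
                    spec.annual_death_probability(age), t_end - t, dpy
                )
                died = occ * q_cycle
                occ -= died
                dead += died
            t = t_end
            cycle += 1

    columns = [
        "slice",
        "cycle",
        "state",
        "t_start_days",
        "t_end_days",
        "occupancy",
        "dead",
        "dqaly",
        "dcost",
    ]
    records = pd.DataFrame(rows, columns=columns)
    return CohortTrace(records=records, total_qaly=total_qaly, total_cost=total_cost)
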