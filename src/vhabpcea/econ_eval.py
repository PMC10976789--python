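"""Per-arm totals, ICER, and (incremental) net monetary benefit.

Combines acute-tree and Markov results into arm totals, then compares
the intervention (CTZ/TAZ) against the comparator (MEPM):

* ICER = delta cost / delta QALY, with dominance labels when the signs
  make the ratio meaningless;
* NMB(arm) = WTP x QALY - cost; INMB = WTP x dQALY - dcost, so
  INMB > 0 iff ICER < WTP whenever dQALY > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .acute_tree import ArmAcuteOutcome, evaluate_acute
from .cohort_markov import CohortTrace, markov_spec_from, run_cohort
from .parameters import ARMS, Arm, COMPARATOR, INTERVENTION, ParameterSet

__all__ = [
    "ArmResult",
    "CEResult",
    "icer",
    "inmb",
    "nmb",
    "evaluate_arm",
    "evaluate",
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost-effectiveness ratio or a dominance label.

    Returns ``"dominant"`` (cheaper and more effective),
    ``"dominated"`` (costlier and less effective), ``"undefined"``
    (zero QALY difference), or the ratio otherwise.
    """
    if delta_qaly == 0.0:
        return UNDEFINED
    if delta_qaly > 0.0 and delta_cost < 0.0:
        return DOMINANT
    if delta_qaly < 0.0 and delta_cost > 0.0:
        return DOMINATED
    return delta_cost / delta_qaly


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit of one strategy at a willingness-to-pay."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * qaly - cost


def inmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit: WTP x dQALY - dcost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * delta_qaly - delta_cost


@dataclass
class ArmResult:
    """Discounted lifetime totals for one arm with their provenance."""

    arm: Arm
    total_cost: float
    total_qaly: float
    acute: ArmAcuteOutcome
    trace: CohortTrace

    @property
    def acute_cost(self) -> float:
        return self.acute.expected_cost

    @property
    def markov_qaly(self) -> float:
        return self.trace.total_qaly


@dataclass
class CEResult:
    """Two-arm comparison: totals, increments, ICER, NMB at one WTP."""

    cost_intervention: float
    cost_comparator: float
    qaly_intervention: float
    qaly_comparator: float
    wtp: float
    intervention: Arm = INTERVENTION
    comparator: Arm = COMPARATOR

    @property
    def delta_cost(self) -> float:
        return self.cost_intervention - self.cost_comparator

    @property
    def delta_qaly(self) -> float:
        return self.qaly_intervention - self.qaly_comparator

    @property
    def icer(self) -> float | str:
        return icer(self.delta_cost, self.delta_qaly)

    @property
    def inmb(self) -> float:
        return inmb(self.delta_cost, self.delta_qaly, self.wtp)

    def nmb_by_arm(self) -> dict[Arm, float]:
        return {
            self.intervention: nmb(self.cost_intervention, self.qaly_intervention, self.wtp),
            self.comparator: nmb(self.cost_comparator, self.qaly_comparator, self.wtp),
        }

    def summary(self) -> dict[str, object]:
        return {
            "cost_intervention": self.cost_intervention,
            "cost_comparator": self.cost_comparator,
            "qaly_intervention": self.qaly_intervention,
            "qaly_comparator": self.qaly_comparator,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "inmb": self.inmb,
            "wtp": self.wtp,
        }


def evaluate_arm(arm: Arm, params: ParameterSet) -> ArmResult:
    """Acute tree then Markov cohort for one arm; totals are additive."""
    acute = evaluate_acute(arm, params)
    trace = run_cohort(acute.end_states, markov_spec_from(params))
    return ArmResult(
        arm=arm,
        total_cost=acute.expected_cost + trace.total_cost,
        total_qaly=acute.acute_qaly + trace.total_qaly,
        acute=acute,
        trace=trace,
    )


def evaluate(
    params: ParameterSet, wtp: float | None = None
) -> tuple[CEResult, dict[Arm, ArmResult]]:
    """Run the full pipeline for both arms and compare them."""
    arms = {arm: evaluate_arm(arm, params) for arm in ARMS}
    result = CEResult(
        cost_intervention=arms[INTERVENTION].total_cost,
        cost_comparator=arms[COMPARATOR].total_cost,
        qaly_intervention=arms[INTERVENTION].total_qaly,
        qaly_comparator=arms[COMPARATOR].total_qaly,
        wtp=params.settings.wtp if wtp is None else wtp,
    )
    return result, arms
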