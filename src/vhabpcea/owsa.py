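"""One-way (tornado) sensitivity analysis.

Each bounded input is set, alone, to its lower and its upper bound; the
full model is re-evaluated and the incremental net monetary benefit
(INMB) at the willingness-to-pay threshold recorded.  Entries are
returned sorted by the INMB swing (tornado order).

Efficacy bounds that would make cure + mortality on a line exceed 1 are
truncated to the feasible edge and flagged; every sweep operates on a
deep copy, so the base case is never mutated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .econ_eval import evaluate
from .parameters import ParameterSet, UncertainParameter, uncertain_parameters

__all__ = ["TornadoEntry", "run_owsa", "tornado_frame", "plot_tornado"]

logger = logging.getLogger(__name__)

#: efficacy rates are paired with the partner rate on the same treatment
#: line; a swept value may not push their sum past 1
_EFF_PARTNER = {
    "cure_first": "mort_first",
    "mort_first": "cure_first",
    "cure_second": "mort_second",
    "mort_second": "cure_second",
}


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    base_value: float
    lower: float
    upper: float
    swept_lower: float
    swept_upper: float
    inmb_at_lower: float
    inmb_at_upper: float
    truncated: bool

    @property
    def range(self) -> float:
        return abs(self.inmb_at_upper - self.inmb_at_lower)

    @property
    def crosses_zero(self) -> bool:
        lo = min(self.inmb_at_lower, self.inmb_at_upper)
        hi = max(self.inmb_at_lower, self.inmb_at_upper)
        return lo < 0.0 <= hi or lo <= 0.0 < hi


def feasible_value(params: ParameterSet, param_id: str, value: float) -> float:
    """Clamp an efficacy rate so cure + mortality on its line stays <= 1."""
    parts = param_id.split(".")
    if parts[0] != "eff":
        return value
    _, arm, fieldname = parts
    partner = getattr(params.efficacy[arm], _EFF_PARTNER[fieldname]).value
    return min(value, 1.0 - partner)


def apply_value(
    params: ParameterSet, param: UncertainParameter, value: float
) -> tuple[ParameterSet, float]:
    """Deep-copy ``params`` with one input set to (feasibility-clamped) ``value``."""
    clamped = feasible_value(params, param.id, value)
    out = params.model_copy(deep=True)
    param.setter(out, clamped)
    return out, clamped


def run_owsa(params: ParameterSet, wtp: float | None = None) -> list[TornadoEntry]:
    """One-way sweep of every bounded input; entries sorted by descending swing."""
    wtp = params.settings.wtp if wtp is None else wtp
    entries: list[TornadoEntry] = []
    for param in uncertain_parameters(params):
        if not param.in_owsa:
            continue
        inmbs: list[float] = []
        swept: list[float] = []
        for bound in (param.lower, param.upper):
            perturbed, used = apply_value(params, param, bound)
            if used != bound:
                logger.warning(
                    "OWSA: %s bound %.4g truncated to %.4g for feasibility",
                    param.id,
                    bound,
                    used,
                )
            result, _ = evaluate(perturbed, wtp=wtp)
            inmbs.append(result.inmb)
            swept.append(used)
        entries.append(
            TornadoEntry(
                parameter=param.id,
                base_value=param.value,
                lower=param.lower,
                upper=param.upper,
                swept_lower=swept[0],
                swept_upper=swept[1],
                inmb_at_lower=inmbs[0],
                inmb_at_upper=inmbs[1],
                truncated=(swept[0] != param.lower) or (swept[1] != param.upper),
            )
        )
    entries.sort(key=lambda e: (-e.range, e.parameter))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "base_value": [e.base_value for e in entries],
            "swept_lower": [e.swept_lower for e in entries],
            "swept_upper": [e.swept_upper for e in entries],
            "inmb_at_lower": [e.inmb_at_lower for e in entries],
            "inmb_at_upper": [e.inmb_at_upper for e in entries],
            "range": [e.range for e in entries],
            "crosses_zero": [e.crosses_zero for e in entries],
            "truncated": [e.truncated for e in entries],
        }
    )


def plot_tornado(
    entries: list[TornadoEntry], base_inmb: float, path, top: int = 15
) -> None:
    """Horizontal-bar tornado of the ``top`` widest INMB swings."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sel = entries[:top][::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(sel) + 1.5))
    for i, e in enumerate(sel):
        lo = min(e.inmb_at_lower, e.inmb_at_upper)
        hi = max(e.inmb_at_lower, e.inmb_at_upper)
        ax.barh(i, hi - lo, left=lo, color="#4878d0", alpha=0.8)
    ax.axvline(base_inmb, color="k", lw=1, label="base-case INMB")
    ax.axvline(0.0, color="r", lw=1, ls="--", label="INMB = 0")
    ax.set_yticks(range(len(sel)))
    ax.set_yticklabels([e.parameter for e in sel], fontsize=8)
    ax.set_xlabel("INMB (yen)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
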