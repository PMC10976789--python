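"""Probabilistic sensitivity analysis (PSA).

Each uncertain input gets a sampling distribution moment-matched to its
point estimate and 95 % bounds (SE = (upper - lower) / 3.92): beta for
proportions and the non-negative utilities, gamma for durations and
costs, normal for the ventilated-ICU utility (which may be negative).
Draws are independent across parameters; one seeded generator samples
them in a canonical (sorted-id) order, so a seed fully determines the
sequence.  Per draw the whole model is re-evaluated; the cloud of
(dQALY, dcost) points yields the CE plane, the probability each
strategy is optimal at the base willingness-to-pay, and the
cost-effectiveness acceptability curve (CEAC) over a WTP grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .econ_eval import evaluate
from .owsa import feasible_value
from .parameters import (
    BoundsAnomalyWarning,
    DistributionSpec,
    ParameterSet,
    UncertainParameter,
    uncertain_parameters,
)

__all__ = [
    "PSASample",
    "PSAResult",
    "build_psa_specs",
    "sample_value",
    "sample_parameters",
    "run_psa",
    "default_wtp_grid",
    "plot_ce_plane",
    "plot_ceac",
]

logger = logging.getLogger(__name__)

_Z95 = 3.919927969080108  # 2 x 1.959964, width of a 95% normal interval in SEs


def default_wtp_grid() -> np.ndarray:
    """0 to 20 million yen in 500,000-yen steps (covers 3x the threshold)."""
    return np.arange(0.0, 20_000_001.0, 500_000.0)


def _spec_for(param: UncertainParameter) -> DistributionSpec:
    se = (param.upper - param.lower) / _Z95
    if se <= 0.0 or param.family == "fixed":
        return DistributionSpec(family="fixed", value=param.value)
    m = param.value
    if param.family == "beta":
        var = se * se
        if not (0.0 < m < 1.0) or var >= m * (1.0 - m):
            logger.warning(
                "PSA: beta moments unmatchable for %s (mean %.4g, SE %.4g); "
                "falling back to uniform bounds",
                param.id, m, se,
            )
            return DistributionSpec(
                family="uniform", value=m, lower=param.lower, upper=param.upper
            )
    if param.family == "gamma" and m <= 0.0:
        return DistributionSpec(
            family="uniform", value=m, lower=param.lower, upper=param.upper
        )
    return DistributionSpec(
        family=param.family, value=m, lower=param.lower, upper=param.upper
    )


def build_psa_specs(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Distribution spec per uncertain-parameter id, in canonical order."""
    return {p.id: _spec_for(p) for p in uncertain_parameters(params) if p.in_psa}


def sample_value(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value from a moment-matched distribution spec."""
    if spec.family == "fixed":
        return spec.value
    if spec.family == "uniform":
        return float(rng.uniform(spec.lower, spec.upper))
    m = spec.value
    se = (spec.upper - spec.lower) / _Z95
    if spec.family == "beta":
        var = se * se
        nu = m * (1.0 - m) / var - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if spec.family == "gamma":
        shape = (m / se) ** 2
        scale = se * se / m
        return float(rng.gamma(shape, scale))
    if spec.family == "normal":
        return float(rng.normal(m, se))
    if spec.family == "lognormal":
        sigma2 = np.log1p(se * se / (m * m))
        mu = np.log(m) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    raise ValueError(f"unknown family {spec.family!r}")


@dataclass
class PSASample:
    draw: int
    params: ParameterSet
    values: dict[str, float]


def sample_parameters(
    params: ParameterSet, seed: int | np.random.Generator, n: int
) -> Iterator[PSASample]:
    """Yield ``n`` sampled ParameterSets, reproducible under the seed.

    Parameters are drawn in canonical order from one generator.  Draws
    are clamped to the parameter's domain; an efficacy mortality draw
    that would push cure + mortality past 1 is truncated to the
    residual (cure rates are sampled before mortalities on each line).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uncertain = [p for p in uncertain_parameters(params) if p.in_psa]
    specs = {p.id: _spec_for(p) for p in uncertain}
    for i in range(n):
        sampled = params.model_copy(deep=True)
        values: dict[str, float] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BoundsAnomalyWarning)
            for p in uncertain:
                v = sample_value(specs[p.id], rng)
                if p.family == "beta":
                    v = min(max(v, 0.0), 1.0)
                elif p.family == "normal" and p.id == "util.icu_vent":
                    v = min(max(v, -1.0), 1.0)
                elif p.family in ("gamma", "lognormal"):
                    v = max(v, 0.0)
                v = feasible_value(sampled, p.id, v)
                p.setter(sampled, v)
                values[p.id] = v
        yield PSASample(draw=i, params=sampled, values=values)


@dataclass
class PSAResult:
    """CE-plane draws, optimal-strategy probabilities and the CEAC."""

    draws: pd.DataFrame
    wtp: float
    wtp_grid: np.ndarray
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.draws)

    def probability_optimal(self, wtp: float | None = None) -> dict[str, float]:
        """Fraction of draws in which each strategy has the highest NMB."""
        wtp = self.wtp if wtp is None else wtp
        inmb = wtp * self.draws["delta_qaly"].to_numpy() - self.draws[
            "delta_cost"
        ].to_numpy()
        p_int = float(np.mean(inmb > 0.0) + 0.5 * np.mean(inmb == 0.0))
        return {"ctz_taz": p_int, "mepm": 1.0 - p_int}

    def ceac(self) -> pd.DataFrame:
        dq = self.draws["delta_qaly"].to_numpy()
        dc = self.draws["delta_cost"].to_numpy()
        rows = []
        for w in self.wtp_grid:
            inmb = w * dq - dc
            p = float(np.mean(inmb > 0.0) + 0.5 * np.mean(inmb == 0.0))
            rows.append({"wtp": float(w), "p_ctz_taz": p, "p_mepm": 1.0 - p})
        return pd.DataFrame(rows)


def run_psa(
    params: ParameterSet,
    n_iter: int = 1000,
    seed: int = 0,
    wtp_grid: Sequence[float] | None = None,
) -> PSAResult:
    """Sample, evaluate and summarize ``n_iter`` model runs."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    rows = []
    for sample in sample_parameters(params, seed, n_iter):
        result, _ = evaluate(sample.params)
        rows.append(
            {
                "draw": sample.draw,
                "cost_ctz_taz": result.cost_intervention,
                "cost_mepm": result.cost_comparator,
                "qaly_ctz_taz": result.qaly_intervention,
                "qaly_mepm": result.qaly_comparator,
                "delta_cost": result.delta_cost,
                "delta_qaly": result.delta_qaly,
            }
        )
    draws = pd.DataFrame(rows)
    return PSAResult(draws=draws, wtp=params.settings.wtp, wtp_grid=grid, seed=seed)


def plot_ce_plane(result: PSAResult, path, wtp: float | None = None) -> None:
    """Scatter of incremental QALYs vs incremental cost with the WTP ray."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wtp = result.wtp if wtp is None else wtp
    dq = result.draws["delta_qaly"]
    dc = result.draws["delta_cost"]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(dq, dc, s=6, alpha=0.4, color="#4878d0")
    lim = max(abs(dq).max(), 1e-6)
    xs = np.linspace(-lim, lim, 3)
    ax.plot(xs, wtp * xs, "r--", lw=1, label=f"WTP = {wtp:,.0f} yen/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (yen)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(result: PSAResult, path) -> None:
    """Cost-effectiveness acceptability curves for both strategies."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ceac = result.ceac()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["wtp"], ceac["p_ctz_taz"], label="CTZ/TAZ")
    ax.plot(ceac["wtp"], ceac["p_mepm"], label="MEPM")
    ax.axvline(result.wtp, color="k", lw=0.8, ls=":")
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (yen/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
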