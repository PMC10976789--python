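"""Synthetic stand-ins for inputs the analysis needs but no file provides.

Two generators:

* a Gompertz life table -- age-indexed annual death probabilities with
  log-linearly increasing hazard -- standing in for the national (MHLW)
  life table, which must otherwise be supplied as a CSV;
* two-arm trial outcomes -- multinomial draws over {cured, died,
  neither} per arm -- from which cure/mortality point estimates and
  Wilson 95 % confidence intervals are recomputed, emulating the
  structure of the source trial's mITT results.

Both are deterministic under a seed and write plain-CSV files that
``load_parameters`` consumes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .parameters import ARMS, Arm, ParameterSet, RateWithBounds

__all__ = [
    "make_life_table",
    "default_life_table",
    "write_life_table_csv",
    "read_life_table_csv",
    "TrialArm",
    "SyntheticTrialArms",
    "simulate_trial",
    "write_trial_csv",
    "apply_trial_estimates",
]

#: defaults give ~1.0 % annual death probability at age 65 and a 9 %/year
#: log-hazard slope -- the order of magnitude of a high-income-country
#: life table; a stand-in, not national data
DEFAULT_ALPHA_AT_65 = -math.log(0.99)
DEFAULT_BETA = 0.09


def make_life_table(
    alpha: float, beta: float, age_min: int, age_max: int
) -> dict[int, float]:
    """Gompertz life table: q(a) = 1 - exp(-alpha * e^(beta * (a - age_min))).

    ``alpha`` is the annual hazard at the reference age ``age_min``;
    ``beta`` the log-hazard slope per year of age.  Raises if any
    resulting probability reaches 1 within the covered range.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if age_max < age_min:
        raise ValueError("age_max must be >= age_min")
    table: dict[int, float] = {}
    for a in range(age_min, age_max + 1):
        q = 1.0 - math.exp(-alpha * math.exp(beta * (a - age_min)))
        if not (0.0 < q < 1.0):
            raise ValueError(f"annual death probability at age {a} is {q}, outside (0, 1)")
        table[a] = q
    return table


def default_life_table() -> dict[int, float]:
    """The built-in stand-in table covering ages 40-105.

    Calibrated so q(65) is ~1 %: the reference-age hazard is shifted
    from 65 down to 40 along the same Gompertz slope.
    """
    alpha_40 = DEFAULT_ALPHA_AT_65 * math.exp(-DEFAULT_BETA * 25)
    return make_life_table(alpha_40, DEFAULT_BETA, 40, 105)


def write_life_table_csv(table: Mapping[int, float], path: str | Path) -> None:
    """Two-column CSV (age, annual death probability), 1-year steps."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["age", "annual_death_probability"])
        for age in sorted(table):
            w.writerow([age, repr(table[age])])


def read_life_table_csv(path: str | Path) -> dict[int, float]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return {int(r["age"]): float(r["annual_death_probability"]) for r in rows}


@dataclass(frozen=True)
class TrialArm:
    """Counts and derived estimates for one synthetic trial arm."""

    n: int
    n_cured: int
    n_died: int
    cure_rate: float
    mort_rate: float
    cure_ci: tuple[float, float]
    mort_ci: tuple[float, float]


@dataclass(frozen=True)
class SyntheticTrialArms:
    arms: dict[Arm, TrialArm]
    seed: int


def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def simulate_trial(
    true_cure: float | Mapping[Arm, float],
    true_mort: float | Mapping[Arm, float],
    n_per_arm: int,
    seed: int,
) -> SyntheticTrialArms:
    """Simulate per-arm multinomial outcomes over {cured, died, neither}.

    ``true_cure``/``true_mort`` may be scalars (both arms share the
    truth) or per-arm mappings.  Returns counts, observed proportions
    and Wilson 95 % intervals per arm; identical seeds give identical
    counts.
    """
    rng = np.random.default_rng(seed)
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    arms: dict[Arm, TrialArm] = {}
    for arm in ARMS:
        pc = true_cure[arm] if isinstance(true_cure, Mapping) else true_cure
        pm = true_mort[arm] if isinstance(true_mort, Mapping) else true_mort
        if not (0.0 <= pc <= 1.0 and 0.0 <= pm <= 1.0 and pc + pm <= 1.0):
            raise ValueError(
                f"infeasible true rates for {arm}: cure {pc}, mortality {pm}"
            )
        counts = rng.multinomial(n_per_arm, [pc, pm, 1.0 - pc - pm])
        n_cured, n_died = int(counts[0]), int(counts[1])
        arms[arm] = TrialArm(
            n=n_per_arm,
            n_cured=n_cured,
            n_died=n_died,
            cure_rate=n_cured / n_per_arm,
            mort_rate=n_died / n_per_arm,
            cure_ci=_wilson(n_cured, n_per_arm),
            mort_ci=_wilson(n_died, n_per_arm),
        )
    return SyntheticTrialArms(arms=arms, seed=seed)


def write_trial_csv(trial: SyntheticTrialArms, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "arm", "n", "n_cured", "n_died",
                "cure_rate", "cure_lower", "cure_upper",
                "mort_rate", "mort_lower", "mort_upper",
            ]
        )
        for arm, t in trial.arms.items():
            w.writerow(
                [
                    arm, t.n, t.n_cured, t.n_died,
                    t.cure_rate, t.cure_ci[0], t.cure_ci[1],
                    t.mort_rate, t.mort_ci[0], t.mort_ci[1],
                ]
            )


def apply_trial_estimates(
    trial: SyntheticTrialArms, base: ParameterSet
) -> ParameterSet:
    """ParameterSet with first-line efficacy replaced by trial estimates.

    Second-line rates are left at the base values; the result passes
    full validation (an estimate pair with cure + mortality > 1 cannot
    arise from a multinomial draw).
    """
    out = base.model_copy(deep=True)
    for arm, t in trial.arms.items():
        eff = out.efficacy[arm]
        out.efficacy[arm] = type(eff)(
            cure_first=RateWithBounds(
                value=t.cure_rate, lower=t.cure_ci[0], upper=t.cure_ci[1]
            ),
            mort_first=RateWithBounds(
                value=t.mort_rate, lower=t.mort_ci[0], upper=t.mort_ci[1]
            ),
            cure_second=eff.cure_second,
            mort_second=eff.mort_second,
            discharge_fraction_if_cured=eff.discharge_fraction_if_cured,
        )
    return out
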