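# Methods

## Model structure

Two strategies — ceftolozane/tazobactam (CTZ/TAZ) and meropenem (MEPM) —
are compared for ventilated HABP/VABP from the health-care payer
perspective, direct medical costs only, in 2022 yen.

**Acute phase (decision tree).** Per arm, with first-line cure rate c₁ and
mortality m₁ (both marginal over all treated patients), the residual
p₂ = 1 − c₁ − m₁ enters second-line therapy (first-line drug + amikacin).
Second line likewise ends in cure (c₂), death (m₂) or long-term ICU care
(1 − c₂ − m₂), the latter modelled as one terminal ICU month followed by
death. Cured patients split between direct discharge (fraction f: 50.6 %
CTZ/TAZ, 56.7 % MEPM) and a one-month general-ward stay.

Costs of a treatment line are incurred by *every* patient entering that
line, cured or not (administration duration does not depend on outcome).
Component conventions:

* drug: daily price × administration days; second line adds amikacin's
  daily price over the same course;
* ventilation: two-tier daily tariff — 9,500 yen/day through day 14
  (first line), 8,150 yen/day from day 15 (second line, which always falls
  past day 14 cumulatively);
* hospitalization: per-arm per-line scalar inputs (the underlying daily
  tariff decomposition is not an input);
* adverse events: Σ incidence × per-event treatment cost; second line adds
  the amikacin nephrotoxicity term (6 % × 94,800 yen);
* long-term care: 495,000 yen per ward month (weighted by the probability
  of a ward stay) and per long-term-ICU month (weighted by
  p₂ × (1 − c₂ − m₂)).

Acute QALYs count all ICU time (first-line length of stay for everyone,
+21 days for second-line entrants, +1 terminal month for long-term ICU) at
the ventilated-ICU utility −0.39/yr, undiscounted — the acute phase sits
inside year 0, where the distortion at 2 %/yr is < 0.6 %.

**Division of labour for the ward month.** The tree charges the ward *cost*
(so the cost breakdown mirrors the published component table), while the
Markov engine owns the ward month's *utility and mortality*: `InWard` lasts
exactly one 30-day cycle at u = 0.77/yr with a one-off 7.6 % in-hospital
mortality, after which survivors become `DischargedAlive`. Counting the
ward month in both places would double-count it; this split keeps each
quantity in exactly one component.

**Long-term phase (Markov cohort).** The tree hands over cohort slices
(state, probability, elapsed days since treatment start). Each slice is
propagated in 30-day cycles until 5 years from treatment start (the final
cycle is truncated). Discharged patients die at the life-table annual
probability for their current integer age, converted per cycle as
1 − (1 − q)^(days/365.25); age advances with elapsed time. QALYs accrue as
start-of-cycle occupancy × utility × cycle-years, discounted at the cycle
midpoint with factor (1 + r)^(−t). No half-cycle correction is applied;
deaths are effectively end-of-cycle, a small (< 1 %) upward bias on
life-years that is symmetric across arms. No post-discharge costs accrue.

## Key parameters (defaults)

| parameter | default | units | note |
|---|---|---|---|
| horizon | 5 | years | from treatment start |
| cycle length | 30 | days | also the model's "one month" |
| discount rate | 0.02 | /year | swept 0–0.04 in OWSA |
| WTP threshold | 5,000,000 | yen/QALY | Japanese scheme |
| cohort start age | 65 | years | not stated in the source; configurable |
| ward mortality | 0.076 | per stay | applied once in the ward month |
| second-line penalty | −10 % cure, +20 % mortality | relative | derivation mode, off by default |
| utilities | −0.39 / 0.77 / 0.80 | /year | ICU-ventilated / ward / discharged |

The built-in fixture carries the published first- *and* second-line rates
directly; the derivation mode (`derive_second_line`) reproduces the +20 %
mortality rule (0.201 → 0.2412, 0.255 → 0.306) but is off by default
because the published second-line cure rates (56.8 / 52.8 %) are not equal
to c₁ × 0.9 — the printed values win. Two published bound pairs are
anomalous (lower bound above the point estimate, an artefact of the
source's digit grouping); they are stored as printed and flagged with
`BoundsAnomalyWarning`, never silently repaired.

Mortality is read as *marginal* (all-cause, all randomized patients), so the
second-line branch receives 1 − c − m; a conditional-on-non-cure reading is
available via `settings.mortality_conditional_on_noncure`.

## Sensitivity analyses

A single registry (`uncertain_parameters`) enumerates every input with
published bounds, in sorted-id order: 8 efficacy rates, 12 durations, the
amikacin AE rate, 3 AE costs, 3 utilities, plus the discount rate
(OWSA-only). Inputs without bounds (drug prices, hospitalization costs,
tariffs, discharge fractions, ward mortality) stay fixed.

**OWSA** re-evaluates the full model at each bound with all else at base
values, reporting INMB at the WTP. A bound that would make cure + mortality
exceed 1 (e.g. MEPM cure upper 0.75 with mortality 0.255) is truncated to
the feasible edge and flagged. Sweeps run on deep copies; the base case is
bit-identical afterwards.

**PSA** assigns, by health-economics convention: beta to proportions and the
two non-negative utilities, gamma to durations and costs, normal to the
ventilated-ICU utility (support includes negative values). All are
moment-matched to (point estimate, SE) with SE = (upper − lower)/3.92,
reading the bounds as a 95 % interval; AE costs print only an upper bound,
so the value doubles as the interval's lower edge. Unmatchable beta moments
fall back to uniform(lower, upper) with a warning. Draws are independent
(no correlation structure is published), taken from one seeded PCG64
generator in canonical order, and clamped to their domain; a mortality draw
is truncated so cure + mortality ≤ 1 (cures are sampled first). Ties in NMB
split probability equally. The CEAC grid runs 0–20 M yen in 0.5 M steps.

## Synthetic data

`synthetic.make_life_table` builds a Gompertz table
q(a) = 1 − exp(−α·e^(β(a−a₀))); the default stand-in uses β = 0.09/yr and
α calibrated to q(65) = 1.0 %, ages 40–105 — the order of magnitude of a
high-income-country national life table, standing in for the official
(MHLW) table which is not redistributable here. It reproduces the *shape*
of real background mortality but not its level by sex, cohort effects, or
the sub-1 % old-age plateau details; green tests therefore establish the
engine's correctness, not calibration to Japanese vital statistics. Supply
a real table (two-column CSV, 1-year steps) via config for applied use.

`synthetic.simulate_trial` draws per-arm multinomial outcomes over
{cured, died, neither} and recomputes point estimates with Wilson 95 %
intervals, emulating the statistical structure of the source trial's mITT
arms (n ≈ 360 per arm); it does not reproduce patient-level covariates,
site effects or non-independence between cure and death times.

## Numerical choices

* 365.25 days/year everywhere; "one month" = one cycle = 30 days.
* Initial distributions must sum to 1 within 1e-9; per-cycle occupancy is
  conserved to < 1e-12 (tested).
* ICER returns dominance labels ("dominant", "dominated", "undefined")
  instead of meaningless ratios; INMB is always the finite alternative.
* Derived second-line rates outside [0, 1] are clamped with a warning.
* Expected acute cost equals a brute-force enumeration of all seven
  root-to-leaf paths to 1e-9 relative error (tested).

## Limitations

* The long-term phase carries no disease-specific excess mortality or
  post-discharge costs: survivors rejoin background mortality.
* Sampling distributions for the PSA are reconstructed conventions, not the
  original (unpublished) assignments; the PSA's *location* (mean increments,
  CE-plane centre) is well determined by the inputs, but its *spread* —
  and hence the probability-optimal figure and CEAC plateau — depends
  strongly on those assignments and carries the reconstruction uncertainty.
* No multi-strategy frontier (exactly two arms), no EVPI/EVPPI, no
  transmission or resistance-emergence dynamics, no currency conversion.
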