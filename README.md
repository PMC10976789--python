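# vhabpcea

Cost-effectiveness model of **ceftolozane/tazobactam (CTZ/TAZ) versus
meropenem (MEPM)** for ventilated hospital-acquired / ventilator-associated
bacterial pneumonia (vHABP/VABP), from the Japanese health-care payer
perspective.

Severe gram-negative pneumonia in ventilated ICU patients is commonly
treated with carbapenems; CTZ/TAZ is a carbapenem-sparing alternative with
comparable trial efficacy but a much higher drug price. This package asks
whether the price premium is justified by the extra cures — fewer second-line
courses, fewer deaths — at Japan's willingness-to-pay (WTP) threshold of
5,000,000 yen per quality-adjusted life-year (QALY).

## Model

A hybrid decision-tree + Markov cohort model:

* **Acute phase (decision tree).** Patients enter ventilated in the ICU on
  first-line therapy. Each line ends *cured* / *died* / *neither*; the
  residual moves to second line (first-line drug + amikacin, 21 extra ICU
  days), and second-line failures spend a terminal ICU month before dying.
  Cured patients are discharged home or spend one month on a general ward.
  Costs (drug, hospitalization, two-tier ventilation tariff, adverse-event
  treatment, long-term care) and ICU-time QALYs (at a negative ventilated-ICU
  utility, u = −0.39) accrue here.
* **Long-term phase (Markov cohort).** States {DischargedAlive, InWard,
  Dead}, 30-day cycles to a 5-year horizon from treatment start. The ward
  month carries a 7.6 % in-hospital mortality; discharged patients face
  age-dependent background mortality from a life table. Costs and QALYs are
  discounted at 2 %/year.
* **Decision metrics.** ICER = ΔC/ΔE; net monetary benefit
  NMB = λ·E − C; INMB = λ·ΔE − ΔC with λ the WTP.
* **Sensitivity analyses.** One-way (tornado, INMB range per parameter) and
  probabilistic (beta/gamma/normal distributions moment-matched to the 95 %
  bounds, 1,000 draws → CE plane, CEAC, probability each strategy is
  optimal).

All published input-table values ship as a built-in fixture
(`vhabpcea.paper_fixture()`); any input can be overridden through a YAML/JSON
config file. The national life table is not redistributable here, so a
synthetic Gompertz stand-in (q₆₅ ≈ 1 %/yr) is generated by
`vhabpcea.synthetic`; supply a real table via config for production use.

## Worked example

```bash
$ vhabpcea base-case --outdir results/
dCost = 425,922.23 yen, dQALY = 0.1634, ICER = 2,606,791 yen/QALY, INMB = 391,025.09 yen
```

CTZ/TAZ costs ≈ 426 k yen more per patient over 5 years (the drug premium,
partly offset by fewer second-line courses and ward stays) and yields ≈ 0.16
extra QALYs (mostly survival), an ICER of ≈ 2.6 M yen/QALY — below the 5 M
threshold, so CTZ/TAZ is cost-effective in the base case (INMB > 0).
`results/` also receives a per-component cost breakdown and a manifest.

```bash
$ vhabpcea owsa --outdir results/ --plot
28 parameters swept; 4 INMB sign change(s)
```

The tornado is dominated by the MEPM first-line cure rate; the conclusion
flips (INMB < 0) within the plausible ranges of the MEPM cure/mortality and
CTZ/TAZ mortality rates.

```bash
$ vhabpcea psa --outdir results/ --seed 1 --iterations 1000 --plot
P(CTZ/TAZ optimal at 5,000,000 yen/QALY) = 70.1% (1000 draws)
```

Equivalently in Python:

```python
import vhabpcea as v

params = v.paper_fixture()
result, arms = v.evaluate(params)
print(result.icer, result.inmb)
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the base-case ICER, incremental cost and
incremental QALYs (full tree + Markov pipeline on the built-in inputs) and
the PSA probability that CTZ/TAZ is optimal at the 5 M-yen threshold
(1,000 seeded draws), writing one JSON object keyed by target id.

See `docs/methods.md` for the modelling assumptions, parameter conventions
and known limitations.
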