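# acs-cea

Lifetime cost-effectiveness of 12 months of **ticagrelor + ASA versus
clopidogrel + ASA after acute coronary syndrome (ACS)** in the German
statutory-health-insurance setting, as a tested, configurable Python
package.

Health-economic modellers and HTA analysts can use it to reproduce,
stress-test and extend a classic decision-tree + Markov cohort analysis:
the first post-ACS year is a decision tree parameterised with trial
outcomes (non-fatal MI, non-fatal stroke, death, with EQ-5D utilities);
survivors then age through an annual-cycle Markov model with states
no event → non-fatal MI / non-fatal stroke → death, Weibull-extrapolated
event probabilities held constant beyond year 2, and background mortality
from a life table combined with a fatal-CV hazard and inflated by
post-event hazard ratios HR (1.6 and 1.4 for the first and later years
after MI; 3.23 and 1.5 after stroke).

For arm *j* with discounted lifetime cost `C_j`, life-years `E_j` and
QALYs `Q_j`, the model reports increments `ΔC = C_T − C_C`,
`ΔE`, `ΔQ` and the incremental cost-effectiveness ratios
`ICER = ΔC/ΔE` (EUR per life-year gained) and `ΔC/ΔQ` (EUR per QALY),
with dominance flagged instead of an ICER when one strategy is both
cheaper and more effective. Uncertainty is handled by one-way scenario
analysis (drug prices, hazard-ratio sets, discount rates, cost toggles,
tornado ordering) and a seed-reproducible probabilistic sensitivity
analysis with cost-effectiveness acceptability curves.

Because the original patient-level data are not public, the package ships
a synthetic-data module that generates trial-like individual patient data
(competing Weibull event times, administrative censoring at the 6-, 9- and
12-month visits) and calibrated life tables, so every stage — including
the censored Weibull maximum-likelihood fit — is testable offline.

## Worked example

```python
from acs_cea import default_configs, bundled_life_table, run_cea

cfg = default_configs()["overall"]          # overall ACS cohort, low-dose ASA
lt = bundled_life_table("german_2009")      # synthetic German 2009 reconstruction
res = run_cea(cfg, lt)
print(f"ticagrelor:  EUR {res.ticagrelor.cost:.0f}, "
      f"{res.ticagrelor.life_years:.4f} LY, {res.ticagrelor.qalys:.4f} QALY")
print(f"clopidogrel: EUR {res.clopidogrel.cost:.0f}, "
      f"{res.clopidogrel.life_years:.4f} LY, {res.clopidogrel.qalys:.4f} QALY")
print(f"increments:  EUR {res.delta_cost:.0f}, {res.delta_ly:.4f} LY, "
      f"{res.delta_qaly:.4f} QALY")
print(f"ICER: EUR {res.icer_ly:.0f}/LY, EUR {res.icer_qaly:.0f}/QALY")
```

prints

```
ticagrelor:  EUR 11521, 12.2291 LY, 10.2110 QALY
clopidogrel: EUR 11087, 12.0474 LY, 10.0528 QALY
increments:  EUR 433, 0.1817 LY, 0.1582 QALY
ICER: EUR 2384/LY, EUR 2739/QALY
```

That is: over a lifetime, one year of ticagrelor costs an extra ~EUR 433
per patient and gains ~0.18 life-years (~0.16 QALYs), about EUR 2,400 per
life-year gained — far below conventional European willingness-to-pay
benchmarks of EUR 25,000–38,000. At the branded clopidogrel price
(2.38 EUR/day instead of the generic 0.72) ticagrelor becomes dominant
(cheaper *and* more effective).

The same analyses are scripted end-to-end under `analysis/`
(01 survival calibration, 02 base case for all three cohorts,
03 scenario/tornado analysis, 04 PSA + CEAC; outputs under `results/`)
and available from the shell:

```bash
acs-cea base-case --cohort overall --out results/base
acs-cea scenarios --scenario-set paper_univariate --out results/scen
acs-cea psa --iterations 10000 --seed 1 --thresholds 0:50000:1000 --out results/psa
acs-cea synth --n 10000 --seed 1 --out results/ipd
```

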