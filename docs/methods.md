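# Methods

## Model overview

`acs_cea` implements a two-part decision-analytic model estimating the
lifetime cost-effectiveness of 12 months of ticagrelor + ASA versus
clopidogrel + ASA after acute coronary syndrome (ACS), from the perspective
of the German statutory health insurance, in 2009 EUR.

**Year 1 — decision tree.** Each arm's first year is summarised by the
trial-observed probabilities of non-fatal myocardial infarction (MI),
non-fatal stroke and all-cause death, with branch-specific utilities.
First-year life-years credit decedents half a year; the death-branch utility
is the observed average accrual of decedents and is therefore used as-is
rather than multiplied by time alive.  Costs comprise the first-post-event
year cost of MI/stroke, a one-off death cost, and drug cost
(`drug_days x daily therapy cost`), with decedents accruing
`drug_death_fraction` (default 0.5) of a treatment year.

**Years 2+ — Markov cohort model.** Annual cycles, states
`no_event`, `mi_y1`, `mi_post`, `stroke_y1`, `stroke_post`, `dead`.
`mi_y1`/`stroke_y1` are one-cycle tunnel states giving the first post-event
year its own mortality hazard ratio and cost.  From `no_event` the annual
probabilities `q_mi`, `q_stroke` (held constant beyond year 2, the Weibull
extrapolation they derive from) route survivors into the tunnels; after a
non-fatal event no further events occur, so post-event states exit only
through death.  Transition probabilities are treatment-independent: the
arms differ solely through their year-1 end distributions.

**Mortality.** The sex-weighted life-table probability and the annual
fatal-CV probability `q_cv_fatal` are combined on the hazard scale
(`h = -ln(1-q)`), and the combined hazard is multiplied by the state's
hazard ratio: base case 1 / 1.6 / 1.4 / 3.23 / 1.5 for
no-event / MI year 1 / MI later / stroke year 1 / stroke later, with the
multinational-model alternative (2 / 6 / 3 / 7.43 / 3) as a scenario.
Whether the HRs should multiply only the life-table component is not
decidable from the source; multiplying the combined hazard is the simpler,
conservative single-knob convention and fits the published results better
(tested during development).  Note the life table is an all-cause table, so
adding `q_cv_fatal` double-counts some cardiovascular deaths; the published
analysis makes the same deliberately conservative choice.

## Timing conventions

These were genuinely open choices; the set below reproduces the published
per-arm life-years to within ~1%, and each is configurable or localised in
one function:

* **Reward timing.** Trace row `t` is the state distribution at the *start*
  of Markov cycle `t` (row 1 = the decision-tree end distribution), and all
  of cycle `t`'s rewards — life-years, QALYs, state costs — accrue on that
  distribution.  Everyone alive at a cycle's start is credited the full
  cycle, i.e. deaths are booked at cycle end; there is no separate
  half-cycle correction.  Consequently the year-1 event survivors spend
  cycle 1 in the tunnel states, where the first-post-event-year hazard
  ratio *and* the first-year event cost apply to them.
* **Discounting.** Year 1 carries discount index 0 (undiscounted); Markov
  cycle `t` is discounted by `(1+r)^-t`, costs and effects both at 3% in
  the base case (0% and 5% as scenarios).
* **Ages.** The cohort enters at `start_age` (default 62; the source does
  not print it, 62 is trial-typical) and cycle `t` spans age
  `start_age + t`; utility age bands (60-69 / 70-79 / 80+) switch at exact
  ages 70 and 80; ages below 60 use the 60-69 band.  The horizon is
  `max_age` 110, where the life table forces `qx = 1`.
* **Death cost.** EUR 8,650 is charged to first-year decedents in the
  decision tree.  It is *not* charged for deaths in the Markov phase by
  default: charging it every cycle inflates per-arm lifetime costs by
  roughly 40% beyond the published totals, while year-1-only charging
  matches them, and the source describes the amount as applied to deaths
  as observed in the trial (i.e. year 1).  The alternative convention
  remains available via `analysis.charge_death_cost_in_markov`.
* **Within-cycle ordering.** Death acts first; the event probabilities
  split the survivors.  This keeps row sums exactly 1 and is verified
  against a micro-simulation oracle that applies the same rules to 10^6
  independent patients.

## Survival calibration

First-year and extrapolated probabilities both come from Weibull models
`S(t) = exp(-(t/lambda)^k)`:

* `calibrate_from_probs(p1, p2)` inverts the printed pair (first-year
  probability, conditional second-year probability) exactly via
  `2^k - 1 = ln(1-p2)/ln(1-p1)`; equal probabilities give `k = 1`
  (exponential) exactly.  For the overall-cohort clopidogrel MI pair
  (0.049, 0.021) this yields `k ~ 0.508` — a strongly front-loaded hazard,
  as expected immediately after ACS.
* `fit_weibull_mle` is a hand-written maximum-likelihood fit on
  (log k, log lambda) (BFGS with analytic gradient, gradient tolerance
  1e-8, iteration cap 500), treating other endpoints and administrative
  censoring as right-censored, with the observed-information covariance on
  the log scale.  It is written in-house because the probabilistic
  analysis consumes exactly this log-scale covariance; `lifelines` serves
  as an independent oracle in the tests (Weibull fit agreement to 0.1%,
  Kaplan-Meier survival comparison within Greenwood error), never as the
  implementation.

## Synthetic data

The trial's patient-level data are not public, so the generator emulates
them: one latent Weibull time per endpoint (shape from the printed year-2
conditional probabilities, scale calibrated), earliest latent time wins,
administrative censoring at the 6-, 9- or 12-month visit with mix
(0.2, 0.2, 0.6) mimicking the event-driven stopping rule, times on a
1-day grid.  Calibration targets the *marginal* 12-month incidences under
competing risks via a fixed-point adjustment (<= 5 rounds, 0.1% absolute
tolerance).  The generator reproduces the configured incidences and the
printed probabilities' temporal shape, but not covariates, regions,
adverse events or non-administrative dropout — so passing tests validate
the model mechanics and the fitting pipeline, not trial realism.

The bundled `german_2009` life table is a synthetic reconstruction, not a
transcription: log-linear interpolation over age anchors with sex-specific
levels calibrated to published German 2009/11 remaining life expectancies
(e60 21.3/25.0, e65 17.5/20.7 years; implied e0 77.8/82.7).  A fully
synthetic Gompertz-Makeham table (`a = 5e-5`, `b = 3.5e-5`, `c = 0.095`)
is available as `synthetic_default` and is used in small test fixtures.

## Probabilistic sensitivity analysis

The source quantifies no parameter uncertainty (no SEs, CIs or covariance
matrices), so the PSA defaults are explicitly *synthetic*:

* hazard ratios: log-normal, median at the base value, log-SD 0.2069
  (95% interval spanning HR/1.5 to 1.5xHR); the no-event HR is the
  reference and is held at 1;
* first-year probabilities: multivariate-normal draws of the log-Weibull
  coefficients, centred on the calibrated base-case values with covariance
  estimated once by fitting synthetic patient-level data of 20,000
  patients/arm (roughly trial-sized subgroups); the baseline standard-normal
  deviate is shared between arms per endpoint, with an independent
  effect deviate for ticagrelor, preserving the correlation between
  baseline risk and effect size.  The year-2 probabilities are recomputed
  from the clopidogrel draw, mirroring the base model's extrapolation.
  A beta alternative (`probability_beta`, effective sample size 6,500) is
  available; an infinite effective sample size degenerates exactly to the
  base case, which the zero-variance collapse test exploits;
* utilities and decrements: beta distributions matched to mean and SE 0.02;
* costs: fixed (treated as known with certainty).

Draws depend only on `(seed, index)` (via `numpy` `default_rng([seed,
index, attempt])`), so results are reproducible bit-for-bit and independent
of execution order; invalid draws (probability sums above 1) are redrawn up
to 100 times.  Because the uncertainty magnitudes are synthetic, the
acceptability-curve outputs are checked qualitatively (monotonicity,
collapse, reproducibility, unbiasedness of the mean deltas), not against
the published percentages.

## Problem sizes and numerics

Default runs use the full lifetime horizon (48 cycles from age 62).  The
analysis scripts use 50,000 patients/arm for the Weibull validation and
2,000 PSA draws; the CLI defaults to the published 10,000 draws.  Markov
row sums are exact by construction and asserted to 1e-12; the calibration
round-trip is exact to 1e-10; cohort extinction is declared below living
occupancy 1e-9.  `cohort_scale` is a pure normalisation and never enters
the arithmetic, which the ICER-invariance test pins down.

## Known limitations

* The reconstruction cannot match the unpublished internals exactly: with
  the calibrated life table the overall and NSTEMI/UA results land within
  ~1% of the published values, but the STEMI incremental cost computes
  ~EUR 30 (~11%) low, leaving the STEMI ICER just outside the ±10%
  reproduction band (~1,263 vs 1,426 EUR/LY).  The discrepancy is confined
  to that subgroup's cost delta and most plausibly reflects the exact life
  table and unrounded inputs of the original implementation.
* No recurrent events, treatment switching, varying treatment duration,
  bleeding/dyspnea adverse-event states, or indirect-cost base case — all
  excluded by the source model's design.
* The no-event annual-cost scenario uses an assumed EUR 974/year
  (GP/cardiologist follow-up) because the source's mapping of that
  scenario's values is ambiguous.
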