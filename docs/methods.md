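# Methods

This note documents the model's assumptions, default parameters, numerical
choices, and limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model structure

The simulation is an annual-cycle, open-cohort microsimulation with three
layers:

1. **Demography.** Each year resolves, in fixed order: ageing, births,
   net migration, background mortality, then disease events. The order is a
   convention; with annual time steps and small rates the ordering effect
   is second-order. Background mortality excludes the modelled cancer
   deaths to avoid double counting; cancer deaths are resolved by the
   disease layer and enter the same headcount ledger, which satisfies
   `N(t+1) = N(t) + births + immigrants − emigrants − deaths` exactly every
   year. Rows are never deleted: dead and emigrated individuals remain in
   the arrays so that positionally indexed random streams stay aligned
   between paired runs.

2. **Risk factors.** Each individual is permanently allocated to one
   quantile per factor (default 5 quantiles, configurable ≥ 2) plus a
   lifelong within-quantile rank fraction. The continuous exposure at any
   age is interpolated from the quantile edges of the *current* age-sex
   cell, so exposures age realistically while the allocation never
   changes. Newborns and immigrants draw quantiles uniformly at entry.

3. **Disease.** Annual incidence is a Bernoulli draw at the calibrated
   hazard `baseline(age, sex) × RR_individual / meanRR(band, sex)`. The
   mean-RR denominator is recomputed every year over the currently at-risk
   population but always from *baseline* (intervention-free) quantiles:
   renormalizing against intervention-shifted exposures would cancel the
   policy's effect on total incidence by construction, because the
   calibration would re-anchor to the shifted mix. New cases draw a 5-year
   fatality outcome immediately; predicted deaths are spread over years
   0–4 after diagnosis by strictly decreasing weights; survivors of five
   full years are recovered (remission), cost nothing thereafter, and
   cannot be re-diagnosed with the same site (no second primaries).
   Concurrent different cancers are allowed and drive the multimorbidity
   cost term. Within-5-year death timing does not vary with age at
   diagnosis (a deliberate simplification mirrored from the modelling
   tradition this package follows).

## Intervention mechanics

Policies modify exposed individuals' continuous exposures: relative BMI or
alcohol changes, relative activity increases, or absolute sedentary-minute
reductions (−72.78 min per 8-h workday averaged over a 5-day week, i.e.
−72.78 × 5/7 per calendar day). Exposure is sampled once at the 2019
implementation year (a closed exposed cohort; people ageing into
eligibility later are not re-sampled — a documented simplification).
Effects are evaluated at mid-year offsets of the piecewise-linear effect
schedule (midpoint rule over each simulated year); only the mass-media
schedule decays, all other policies hold full effect for the horizon.
Where the published effect is a range (menu labelling 1.05–1.31 %), each
exposed individual draws uniformly from it; the workplace exposure range
2.31–6.95 % defaults to its midpoint, further thinned by 50 % enterprise
participation.

**Risk transmission.** The effect of a shifted exposure on incidence is
computed continuously: the individual's anchored quantile RR is multiplied
by `exp(g(v′) − g(v))`, where `g` is the piecewise-linear log-RR curve
through the cell's (quantile mean, log RR) points, held flat beyond the end
means. This was chosen over re-binning the shifted value into quantiles
for three reasons: (a) an exactly unchanged exposure gives exactly zero
shift, so a zero-effect policy is bit-identical to business-as-usual under
common random numbers; (b) `g` is monotone, so scaling a harmful-exposure
reduction up never weakens the risk reduction (dominance); and (c) pure
re-binning makes transmission a step function in which a 0.4 % BMI shift
affects only the few percent of exposed individuals adjacent to a bin
edge, suppressing small policy effects by roughly a factor of five relative
to a per-unit (GBD-style) gradient. The flat extension beyond the end
means conservatively gives no marginal effect in the extreme tails.

**Alcohol pricing.** Elasticities vary over beverage × drinker age band ×
drinking category (heavy = baseline intake ≥ 25 g/day); individual
consumption changes are beverage-volume-weighted cell changes. The tax is
a uniform +10 % price change (cell change = elasticity × 0.10). Minimum
unit pricing computes, from the unit-price volume distribution, the
below-floor market share and its mean price uplift; the cell change is
share × uplift × elasticity. Abstainers (zero consumption) are unaffected
because all alcohol effects are multiplicative.

## Default parameters of the synthetic country

All inputs are generated with seed-jittered defaults; none claims fidelity
to a real country.

- **Demography**: Gompertz–Makeham background mortality (Makeham 4e-4;
  Gompertz slope 0.088, male level 3.2e-5 > female 2.0e-5); total
  fertility ≈ 1.7 over maternal ages 15–49; net immigration 0.2 %/yr at
  ages 20–39; stable-population pyramid sampled multinomially so it sums
  to the requested scale exactly.
- **Risk factors** (per age band × sex, 4000-draw generating samples):
  BMI normal (mean 19.5→27.8 over bands, SD ≈ 4); activity gamma (mean
  2800→900 MET-min/wk); sedentary normal (mean 420→600 min/day, SD 110);
  alcohol zero-inflated gamma with a fixed 25 % abstainer share, so the
  bottom quintile is exactly zero at the default 5 quantiles (supported
  for 2–7 quantiles; the youngest band keeps a small drinker mean of
  1 g/day so quantile means stay strictly increasing).
- **Epidemiology**: logistic incidence-by-age curves (e.g. colorectal
  plateau 0.0030/yr male, 0.0022 female around ages 70+; breast female
  only; zero below age 20); 5-year case fatality 0.15 (breast), 0.35
  (colorectal), 0.70 (oesophageal), 0.75 (liver) with a mild age
  gradient; mortality-year weights (0.40, 0.25, 0.15, 0.12, 0.08).
- **Relative risks**: log-linear across quantiles with bottom-quantile
  reference 1; top-quantile values ≈ BMI 1.4–1.6 (all four cancers),
  activity 0.85/0.75 (breast/colorectal, protective), sedentary 1.25
  (colorectal), alcohol 1.4–2.2 (strongest for oesophageal).
- **Costs**: 32–50 k USD PPP per case-year by site; terminal-year
  multiplier ≈ 2.5; multimorbidity increment ≈ 0.25 per additional
  concurrent cancer; disability weights 0.11–0.28.
- **Elasticities**: moderate-drinking cells U(−0.68, −0.52), heavy cells
  U(−0.55, −0.42) — chosen so a +10 % price maps every cell into the
  published 4–7 % consumption-reduction band; unit-price bins
  (0.50, 0.60, 0.80, 1.00, 1.40) with shares (0.10, 0.10, 0.25, 0.30,
  0.25) and a default floor of 0.65, giving a 20 % below-floor share, a
  19.2 % mean uplift, and per-cell cuts of ≈ 1.6–2.6 % (inside the
  published 0.6–3.3 % band). These are calibrations to published effect
  ranges, not estimates.

## Scenario machinery and uncertainty

Every stochastic event class draws from its own PCG64 stream keyed by
(seed, purpose, year), consumed positionally by individual id. Paired runs
therefore share all random inputs (common random numbers), and replicate
seeds are derived from the master seed via `SeedSequence`. Confidence
intervals are percentile intervals over independent replicate outcomes
with the replicate mean as point estimate; they describe run-to-run
variability and are conservative as intervals for the expected value.
Savings are expenditure differences divided by baseline person-years
(end-of-year headcounts), undiscounted; a discount rate is deliberately
not applied because cumulative figures are reported, and costs/DALYs share
the convention.

Problem sizes used by the shipped checks: unit tests run on an 8,000-person
world; the model-consistency suite uses a 100,000-person null run over
2020–2050 for incidence calibration and a battery of 40 paired replicates
at 20,000 people for policy direction and ranking. The replicate count was
sized from the Poisson-scale expected case differences of the weakest
policy (workplace programmes, ~0.1–0.3 avoided cases per 20,000-person
run) so that pooled positivity is detectable.

## What the synthetic data does and does not show

The generator reproduces the *structure* real analyses rely on — age-sex
gradients, fixed quantile allocation, front-loaded cancer mortality,
elasticity heterogeneity — with magnitudes in plausible ranges. It does
not reproduce any specific country's rates, secular trends in risk factors
or incidence, cohort effects, screening, stage at diagnosis, or treatment
change. Passing tests therefore demonstrate the mechanics (calibration,
accounting identities, policy ordering, directionality), not real-world
effect sizes; headline multi-country totals from published analyses are
out of scope at desk scale.

## Known limitations

- Male breast cancer is excluded (incidence forced to zero) to keep the
  RR table compact.
- Risk factors act independently; no cross-factor interactions, and no
  effect of a policy on factors other than its target.
- Annual resolution: the mass-media 1-month peak only enters through the
  mid-year schedule evaluation.
- Intervention delivery costs and labour-market effects are not modelled;
  savings are gross treatment-cost differences.
- Lung and other cancer sites are not modelled.
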