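# Methods

## Model structure and assumptions

The projection is a deterministic, discrete-time (annual cycle) Markov
cohort model over 12 strata (sex × age band, 25–34 … 75+). Five states
per stratum: Healthy, Obese, Smokers (non-obese smokers), Diabetes, and
two absorbing death states (diabetes-related, other causes). Structural
assumptions:

- **Exogenous exposures.** There are no Healthy→Obese or Healthy→Smoker
  transitions; instead the Obese and Smokers pools are re-anchored to
  the exogenous risk-factor trend every cycle. The diabetes pool is the
  only state with memory. Consequence: the model cannot represent
  feedback of diabetes onto future obesity, and exposure history
  (duration, dose) is not modelled.
- **Overlap handling.** Obese smokers are counted as Obese (exposures
  assumed independent: joint prevalence = product). Diabetics
  attributable to an exposure — population attributable risk, Levin's
  formula PAR = p(RR−1)/(1+p(RR−1)) — are removed from that exposure's
  pool so exposure pools are diabetes-free. PAR corrections are applied
  independently per exposure; no joint-exposure PAR. Survey prevalences
  are read as whole-population proportions, because that is what surveys
  measure.
- **Incidence decomposition and anchoring.** The stratum incidence
  input *I* is an overall-population rate. The healthy-state rate is
  *I*ₕ = *I*/(pₕ + p_o·RR_o + p_s·RR_s). The shares (pₕ, p_o, p_s) are
  the start-year post-partition non-diabetic shares, and *I*ₕ is then
  held fixed for the whole run (`incidence_anchor="baseline"`, the
  default). The alternative `per_cycle` re-decomposes against each
  year's shares; it is retained for comparison but largely neutralises
  the risk-factor trends, because the weighted-sum identity then pins
  each cycle's aggregate incident flow to *I* regardless of how the
  exposed pools grow (the residual effect is only the concavity of
  1−exp), which defeats the purpose of a risk-factor-driven forecast
  and can even make the capped scenario infinitesimally *higher* than
  the uncapped one. Baseline anchoring restores the intended behaviour:
  exposure growth raises aggregate incidence through the RR-weighted
  pools.
- **No remission**; case fatality applies in addition to other-cause
  mortality for diabetics.
- **Competing risks** within a cycle use additive hazards converted
  jointly (exit probability 1−exp(−Σh), split h-proportionally). The
  `direct` conversion mode (probability = rate, capped at 1, same
  proportional split) is available for sensitivity to that choice.
- **Population renewal.** `closed_strata` (default): each stratum's
  living compartments are rescaled by a common factor to match the
  exogenous population trajectory; prevalence shares are preserved, no
  inter-band flow. `band_shift` (alternative): 1/10 of each band (1/15
  of the open-ended 75+ band, which exits the modelled ages) moves to
  the next band carrying its compartment mix; entrants to 25–34 fill
  the exogenous deficit with that year's risk-factor mix and a
  configurable diabetes prevalence (default 0); bands are then rescaled
  to the exogenous totals. Neither mode is asserted to be the original
  model's; both satisfy the conservation and start-year invariants.
- Person counts are continuous; no rounding until report formatting
  (percent, half-up, one decimal). Iteration order is fixed (years
  outer, strata inner, men before women, young before old) so reruns
  are bit-identical.

## Parameters

| Parameter | Units | Default | Notes |
|---|---|---|---|
| incidence *I* | events / person-year | sex- and age-specific table (12.9–30.7 per 1000) | disease-model-derived input, stored /1000 |
| case fatality *f* | deaths / person-year | 0.0015–0.0462 | diabetic state only, additional to *m* |
| total mortality *m* | deaths / person-year | 0.0001–0.0116 | applies to every living state |
| RR_obese | — | 6.74 (men), 12.41 (women) | meta-analytic; ≥1 enforced |
| RR_smoker | — | 1.44 (both) | meta-analytic; ≥1 enforced |
| extremes_factor | proportion | 0.20 | analysis-of-extremes scaling |
| cap_male / cap_female | proportion | 0.35 / 0.60 | highest observed obesity by sex |
| rate_conversion | — | exponential | 1−exp(−h) vs direct |
| aging_mode | — | closed_strata | see above |
| incidence_anchor | — | baseline | see above |

All rates live in one canonical unit (per person per year, proportions
in [0,1]); printed per-1000 and percent values are divided on ingestion
to avoid silent 1000× errors.

## Trend construction

Piecewise-linear between survey years. Beyond the last survey the slope
is the first-to-last chord — the single well-defined "overall observed
rate of increase" even when surveys are unevenly spaced (1992/1997/2005
for obesity, 1992/2005 for smoking). Before the first survey the first
segment's slope is used (only relevant when the run starts earlier than
the first survey). Values are clamped to [0,1]; a single survey point
yields a constant series. No smoothing, splines or logistic fitting —
the trends are deliberately linear.

## Synthetic data

The generator emulates the structure of the original inputs, which were
never published at stratum level: linear per-sex risk-factor lines with
multiplicative age gradients, sampled at the survey years with
truncated-normal jitter (default sd 0.005 on the prevalence scale, a
plausible national-survey sampling error); an exponentially growing
population (3.2%/year) on a young-heavy age pyramid totalling 6.5 M
adults in 1992; and an age-increasing baseline diabetes surface rescaled
so the population-weighted 1992 prevalence is exactly 8.5%. Default
calibration puts the 2005 survey values near the published anchors
(≈34.5% male peak-band obesity, ≈58.8% female). What the synthetic
bundles do **not** emulate: survey design effects and non-sampling bias,
non-linear or saturating real-world trends, migration shocks to the
population pyramid, and any correlation between risk factors beyond the
independence assumption. Tests passing on these bundles therefore
demonstrate internal consistency and the model's mathematical
properties, not agreement with the original data.

## Numerical choices and degenerate inputs

- Exposure pools exceeding the non-diabetic mass (possible when
  diabetes is large and PAR small) are shrunk proportionally; healthy
  absorbs the residual and is floored at 0.
- A stratum whose non-diabetic pool is empty reports all-healthy
  exposure shares so the decomposition stays defined.
- An extinct stratum repopulated by the exogenous trajectory re-enters
  as healthy and is re-partitioned the next cycle.
- Scaled proportions in the analysis of extremes are clamped to [0,1]
  and scaled RRs floored at 1; low/high runs scale every parameter
  coherently in one direction — no mixed-direction search for true
  extrema, a conservative simplification of the extremes method.
- The microsimulation oracle uses per-compartment multinomial draws
  (distributionally identical to per-individual Bernoulli transitions)
  with plug-in binomial standard errors √(n p̂(1−p̂)); comparisons use a
  floor of 1 person on the SE to avoid zero-variance corner states.

## Problem sizes

The default run is 12 strata × 31 years; the full projection takes well
under a second. The validation microsimulation uses 200,000 individuals
over 30 years; the conservation property suite runs 100 randomized
bundles end to end; the asymptotic no-mortality check runs a 1200-year
horizon. All sizes were chosen so the statistical checks (3
Monte-Carlo SE; 1e−9 relative conservation) are sharp at negligible
cost.

## Known limitations

- Prevalence forecasts inherit the linear-trend assumption; capping is
  the only non-linearity offered.
- The under-25 population, overweight (BMI 25–29.9), complications,
  treatment effects and costs are out of scope.
- The uncertainty band is an analysis of extremes, not a probabilistic
  interval; it has no coverage interpretation.
- With `band_shift` aging, the entrant diabetes prevalence is a free
  parameter (default 0) because no data inform it.
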