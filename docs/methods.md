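# Methods

## The two-pool DLW model

The package implements the standard two-pool doubly-labelled-water
analysis. Its assumptions are the usual ones: body water is a single
well-mixed pool at steady state over the measurement week; both tracers
are eliminated by first-order kinetics, so excess enrichment above the
participant's pre-dose baseline decays as A·e^(−kt); the deuterium and
oxygen-18 dilution spaces overestimate the true body-water pool by
fixed factors (1.043 and 1.007); and a fixed fraction of water loss is
isotopically fractionated gaseous loss (rGF = 1.05·N_corr·Δ, entering
the CO₂ equation with weight 0.0246). Energy conversion uses a
Weir-type equivalent, kcal per litre CO₂ = 1.106 + 3.94/FQ, in place of
a measured respiratory quotient. Hydration of fat-free mass is fixed at
0.732.

Elimination rates and dilution spaces are estimated by the
slope-intercept method: unweighted OLS of ln(excess) on time in days.
Weighted fits, multi-compartment kinetics and plateau (single-sample)
protocols are out of scope. Dilution spaces follow from the dose:
N = (moles of labelled species administered) / (zero-time intercept as
mole-fraction excess), with molar masses 20.0231 g/mol (²H₂O) and
20.0148 g/mol (H₂¹⁸O). The canonical enrichment unit is mole-fraction
excess; ppm-excess inputs are converted via a declared unit field,
since laboratories report in different conventions.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| food quotient FQ | 0.86 | – | diet-level CO₂/O₂ ratio for populations without dietary assessment (~30% of energy from fat); lowering FQ to reflect a leaner diet lowers TEE by roughly 3–5% |
| hydration constant | 0.732 | kg TBW / kg FFM | adult reference value; override for children or clinical populations |
| dilution-space factors | 1.043 / 1.007 | – | pool-size overestimates of ²H and ¹⁸O; fixed by the method |
| WT fractionation | 0.99 | – | deuterium-flux fractionation correction (division) |
| cut points | 200, 2690 | counts/min | per-minute vector-magnitude thresholds for light and moderate-to-vigorous activity |
| wear marking | 90 min window, 2 min spikes | min | a zero-VM run of ≥90 min, tolerating ≤2-min interruptions, is non-wear |

All constants live in one frozen `DLWConstants` object recorded in every
CLI provenance block; computation is in full double precision with
rounding (4 significant figures) applied only when writing CSVs.

## The reference cohort and one data-quality rule

The packaged table (34 Daasanach adults; 19 women, 15 men; three
communities) carries both the kinetic inputs and the published derived
values, so the pipeline can be checked row by row: fat-free mass
reproduces to ±0.1 kg, water turnover to ±0.01 L/day and TEE to ±1%,
the residual tolerances expected from inputs printed at 4 significant
figures. One row fails an internal self-check — its ND and NO columns
imply a dilution-space ratio of 1.026 while its own printed ratio
column says 1.041 — and no single-field correction makes its derived
values reproducible, so it is a transcription defect in the source
table. Row-level golden comparisons exclude rows flagged by exactly
this data-internal rule (|ND/NO − printed ratio| > 0.002; one row);
aggregate summaries and regressions keep all 34 rows, where the effect
of the defective row is within the stated tolerances.

The functional forms of the CO₂, TEE and water-turnover equations
(averaging the deflated dilution spaces; division by FQ and by the 0.99
fractionation factor) are fixed by exact numerical agreement with this
table; plausible alternative readings (multiplying by the pool factors,
multiplying by 0.99) miss the printed values by 2–5% and are rejected
by the golden tests.

## Cohort statistics

TEE, FFM and FM are natural-log transformed before TEE modelling; FM is
always the pipeline's body mass − FFM. OLS (via statsmodels) uses
treatment coding with reference levels female / Illeret / the home
population, and model selection among nested candidates is by adjusted
R² only. Residuals of the best model serve as composition- and
sex-adjusted TEE in a one-way ANOVA across communities. On the
reference cohort the recomputed best model gives adjusted R² = 0.646
and an lnFFM exponent of 1.32; the ANOVA F (0.57 at n = 34) is
sensitive to the two rows of ambiguous provenance, so it is treated as
a soft check. The Kruskal–Wallis step-count comparison is implemented
generically (df = groups − 1); the published grouping that yields df=2
over four community×sex cells is not identifiable, so no specific H
value is asserted.

Prediction-interval screening takes an external reference model as
named coefficients plus either a full coefficient covariance (exact
half-width √(s² + x′Vx)) or just residual SD and n (mean-covariate
approximation s·√(1+1/n)); the mode is determined by what the config
declares. Published worldwide reference coefficients are external
config, not package data; the machinery is validated by coverage on
synthetic cohorts.

## The synthetic generator

`generate_cohort` draws sex, community, age, body mass and fat% from
truncated normals calibrated to the reference cohort (masses 52.5/49.2
kg, fat 14±6 / 25±8% for men/women, bounds 39–65 kg and 4.5–37.6%),
generates true TEE from the allometric model (intercept 3.35, lnFFM
1.33, lnFM −0.16, male −0.22, log-scale SD 0.14) and water turnover as
3.07 + 0.002·TEE ± 1.8 L/day (floored at 2), then *inverts* the DLW
equations — choosing an ND/NO ratio ~N(1.041, 0.008) truncated to
[1.00, 1.07] and solving for ND, NO, kD, kO — so the forward pipeline
reproduces the truth to machine precision. Washout curves are
mono-exponential over an 8-sample, 7-day schedule with multiplicative
log-normal noise; count streams are bout-structured with class minutes
matching the profile exactly and small movement bouts (longer than the
spike tolerance) embedded in sedentary time so that only labelled
non-wear forms long zero runs.

What the generator does **not** emulate: isotopic plateau and analytic
error structure of a real mass spectrometer, within-week non-steady
states (rehydration events, illness), seasonal variation, correlated
accelerometer axis noise, or diary-level wear behaviour. Passing tests
therefore demonstrate correctness of the computations and estimators
under the stated generative model, not robustness to every field
artefact.

One global seed fans out to per-participant substreams by a stable CRC32
hash of the participant id, so adding a participant never perturbs
another's data.

## Numerical and design choices

- Log-linear OLS via `numpy.polyfit`; R² reported from the log-scale
  residuals; exactly two points reduce to the closed-form slope.
- The 2689/2690 printed ambiguity in the cut points is closed upward:
  light = [200, 2690), MVPA = [2690, ∞), so classes tile all VM values.
- Non-wear never nulls activity classes (non-wear minutes are zero-VM
  and so already sedentary+nonwear); wear flags are reported alongside.
- Days with partial wear are included in participant means.
- Negative fat mass passes through with a warning by default (clamping
  is opt-in): it signals inconsistent inputs rather than a quantity to
  hide.
- Malformed cohort rows are rejected individually with named warnings;
  structural schema problems raise with an itemised list.

## Problem sizes

The test suite and acceptance script run the reference cohort (n = 34),
Monte-Carlo washout recovery at 500–1000 replicates, parameter recovery
at n = 500, prediction-interval coverage at n = 1000, and multi-day
accelerometer streams of 2–9 days (8640 ten-second epochs/day); the
whole suite completes in a few seconds on one CPU.
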