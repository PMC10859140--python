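# Methods

## Model and assumptions

The core model is a two-state continuous-time hidden Markov model (HMM)
over each participant's eGFR sequence. The latent state S(t) ∈ {healthy,
unhealthy} is a Markov jump process with constant intensities q_HU
(healthy→unhealthy) and q_UH (unhealthy→healthy), both per month. The
transition matrix over a gap Δt is the matrix exponential of the
intensity matrix, computed in closed form for two states; missed visits
therefore need no imputation — they only lengthen Δt, and
Chapman–Kolmogorov consistency guarantees the likelihood is the same as
if the missing time points had been marginalised explicitly.

Emissions are Gaussian given the state. The healthy emission
N(μ_H + δ·1[pregnant], σ_H²) is estimated from the data; pregnancy
physiologically raises GFR, so pregnant visits shift only the healthy
mean (by δ, estimated). The unhealthy emission is an *assumed* fixed
Gaussian, default N(85, 25²) mL/min/1.73 m² — broad and centred between
typical observed means of established-disease groups — because cohorts
of this design rarely contain enough confirmed unhealthy person-time to
identify a second free component stably. An optional mode estimates
(μ_U, σ_U) under the ordering constraint μ_U < μ_H − 10, which keeps the
labels identified.

Intensities carry no covariates inside the HMM. Exposure effects are
assessed downstream on the smoothed posteriors, which keeps the state
model a single shared description of kidney-function dynamics and the
risk-factor analysis a separate, clearly specified regression.

## Posteriors and classification

Forward–backward smoothing (scaled recursions; per-step log offsets on
the emission densities so sequences of length 10⁴ cannot underflow)
yields per-visit γ_t = P(unhealthy | full sequence) and per-interval
joint probabilities ξ_t(s, s′). ξ_t(H,U) — the probability of having been
healthy at the previous visit and unhealthy at the current one — is the
"departure from the healthy eGFR distribution" outcome. Smoothing, not
filtering, is used throughout: an isolated low eGFR flanked by healthy
values is discounted by later evidence (the suite verifies smoothed
classification accuracy is never below filtered accuracy).

Classification uses strict thresholds: a visit is labelled unhealthy iff
γ > 0.5, an interval is a probable departure iff ξ_HU > 0.5. Reversion
flags mark healthy-labelled visits after an earlier unhealthy label.

## Estimation

Pooled maximum likelihood across participants, on transformed parameters
(log q_HU, log q_UH, μ_H, log σ_H, δ, logit π_U), with L-BFGS-B and five
multi-starts: the first from moment-based initials (healthy moments from
the upper part of the pooled eGFR histogram; π from the fraction of
baseline values far below it), the rest from seeded perturbations. The
pooled likelihood can be multimodal when the components overlap, hence
the restarts. Participants enter the likelihood with ≥ 4 eGFR measures
after removing held-out visits (default: the final two visits of the
long cohort, kept for descriptive follow-up but excluded from
estimation). The initial distribution π_U is a single free probability
shared across cohorts and sexes; sex-stratified fitting is available as a
configuration option. q_UH is freely estimated (reversion is observed in
this setting), with no hard constraint tying it to q_HU.

Diagnostics report the log-likelihood, convergence flag, per-start
log-likelihoods and the gradient norm at the optimum; a warm-start option
(`init_params`) allows refitting from previous estimates, which changes
the log-likelihood by < 1e−6 at a converged optimum.

## Incidence and Cox analyses

CKD (stages 3–5) is the first of two consecutive *attended* visits with
eGFR < 60; the event time is the first of the pair, and a missed visit
between two low measures does not break consecutiveness (the design
guarantees attended visits are ≥ 6 months apart). Participants below 60
at baseline are prevalent and contribute no risk time, even if they later
rise above 60. Kaplan–Meier estimation is delegated to lifelines with
Greenwood variance reported; incidence-rate CIs use the exact Poisson
(chi-square quantile) method; the Cox model uses lifelines'
counting-process fitter (Efron ties) with baseline, time-updated or
cumulative-exposure-years covariate coding. Time-updated Cox covariates
take the value reported at the visit opening each interval, so they are
known at the start of the risk interval.

## Fractional logit on departure probabilities

The outcome for each interval is ξ_HU ∈ [0, 1]. The quasi-binomial GLM
with logistic link solves Σ xᵢ(yᵢ − μᵢ) = 0, the standard estimator for
fractional outcomes; outcomes of exactly 0 or 1 are admitted. A constant
outcome strictly inside (0, 1) is still estimable (the intercept is its
logit); only boundary-constant outcomes are rejected. Intervals whose
previous-visit γ exceeds 50% (strictly) are censored: the question is
what precedes departure from health, conditioned on having been healthy.
Base adjustment: baseline age, sex, community, visit indicators (the
outcome should not cluster at particular field rounds) and follow-up
duration in months at the interval end; exposures are entered one at a
time on top, with a joint multivariable mode for confounding checks.
Standard errors are sandwich estimates clustered on participant — the
repeated intervals per person make independence implausible — and reduce
to the heteroskedasticity-robust sandwich (up to the usual finite-sample
factor) when every cluster is a single row. No multiple-testing
adjustment is applied; the screen is hypothesis-generating.

## Synthetic cohorts

The generator emulates the study design: a long cohort (default n=351,
10 visits over 84 months on a mixed 6-monthly/annual calendar) and a
short cohort (n=420, 4 annual visits); per-cohort male fractions 0.755
and 0.507; visit months jittered ±1 month; attendance 0.90 (women) /
0.85 (men) with baseline always attended (overall ≈ 0.88); baseline
unhealthy probability 0.17 (men) / 0.02 (women); intensities q_HU =
0.004, q_UH = 0.0005 per month; healthy emission N(123.8, 10.7²) with
pregnancy shift +15.8 (per-visit pregnancy probability 0.05 for women, a
plausible rate for a cohort aged 18–30); unhealthy emission N(85, 25²);
and two default binary exposures, "cramps" (prevalence 0.15, intensity
multiplier 2.25) and "NSAID use" (0.10, 2.10), magnitudes taken from the
scale of reported associations in this setting. Exposures are reported
only at attended visits and refer to the whole period since the previous
attended visit, so the generating intensity multiplier is constant over
each *observed* interval — matching how time-updated questionnaire items
are collected. Serum creatinine is back-computed from the emitted eGFR
by inverting the CKD-EPI equation, so the table reader's fill-in path is
exercised end to end. Identical seeds give byte-identical tables.

What the generator does **not** emulate: questionnaire micro-structure
and correlated exposures, seasonality, assay noise and calibration drift
in creatinine, informative (outcome-dependent) loss to follow-up, and
age/secular trends in healthy eGFR. Passing recovery tests therefore
show the estimators are correct for the assumed data-generating process,
not that the model is unbiased for any real cohort.

## Behaviour of the two-stage odds ratio, and the validation design

A point worth stating explicitly: when the healthy and unhealthy
emission distributions overlap substantially (the study-default
N(123.8, 10.7²) vs N(85, 25²)), the posterior ξ is shrunk toward the
covariate-free prior, and the fractional-logit odds ratio for an
exposure that truly multiplies the transition intensity is *attenuated*.
Measured at the default conditions, a generating multiplier of 2.25
yields a two-stage OR around 1.75, while a regression on the true
transition indicators yields ≈ 2.5 (odds ratios exceed intensity ratios
by Jensen/convexity at non-negligible interval probabilities). The
screen is therefore conservative at realistic overlap — attenuation, not
spurious signal. The odds-ratio recovery experiment consequently uses a
configuration in which the two-stage estimand coincides with the
generating multiplier: well-separated emissions (μ_U = 60, σ_U = 10),
full attendance, one non-null exposure, everything else at study
defaults. Null-exposure coverage of OR = 1 is checked at the study
defaults, where shrinkage does not bias the null.

## Numerical choices

- Transition matrices: closed form; the identity at zero total intensity.
- Scaled forward recursion with per-step max-log-emission offsets; the
  backward pass reuses the forward scalers (Rabiner scaling), so each
  interval's four ξ values sum to one to machine precision.
- Optimiser bounds keep log-rates in [−12, 2] and logits in [−8, 8] to
  avoid overflow; convergence at ftol 1e−12 / gtol 1e−8.
- CKD-EPI inversion: Brent root-finding on the strictly decreasing
  equation, bracketed on creatinine ∈ [1e−4, 60] mg/dL, xtol 1e−12.
- Ties at classification thresholds resolve to the lower state (strict
  `>`), matching the ">50%" convention.
- Pipeline CSV output uses 6-significant-digit formatting, making
  repeated runs byte-identical.

## Problem sizes in the test suite

Recovery experiments use cohorts of 600 participants (parameter
recovery; 20 replicates for the bias check) and the default 771
(odds-ratio recovery and null coverage, 20 replicates each); oracle
checks enumerate all latent paths on 200 random trajectories of length
≤ 6. These sizes give Monte-Carlo error comfortably below the assessed
tolerances while keeping the suite quick to run.

## Known limitations

- Two latent states only; progressive decline within the unhealthy state
  is not modelled.
- Covariates cannot enter the intensities; mechanistic effect estimates
  are attenuated under emission overlap (see above).
- The unhealthy emission is an assumption, not an estimate, by default.
- Exact transition times are never imputed; all inference is at the
  visit grid.
- The fractional logit assumes the smoothed ξ are fixed data; posterior
  uncertainty from the HMM fit is not propagated into the second-stage
  standard errors.
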