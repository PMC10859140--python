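# nephrohmm

Continuous-time hidden Markov modelling of eGFR trajectories for detecting
**early, sustained loss of kidney function** in longitudinal cohorts —
built for epidemiological studies of chronic kidney disease of
undetermined cause (CKDu / Mesoamerican nephropathy), where disease onset
must be separated from exacerbation of established disease and where the
conventional CKD threshold (eGFR < 60 mL/min/1.73 m²) only captures
advanced cases.

## The model

Each participant's serum creatinine is converted to eGFR with the 2009
CKD-EPI equation. A latent two-state Markov jump process in continuous
time — *healthy* (H) and *unhealthy* (U) — evolves with intensities
q_HU, q_UH (per month); over an inter-visit gap Δt the transition matrix is
the closed-form matrix exponential of the 2×2 intensity matrix, so
irregular schedules and missed visits are handled exactly. Observed eGFR
is emitted from state-specific Gaussians: N(μ_H + δ·1[pregnant], σ_H²)
when healthy (pregnancy raises filtration) and a lower-mean N(μ_U, σ_U²)
when unhealthy.

Forward–backward smoothing yields, per visit,

- γ_t = P(S_t = U │ y₁..y_T), the posterior probability of the unhealthy
  state given the *whole* trajectory, and
- ξ_t(H,U) = P(S_{t−1} = H, S_t = U │ y₁..y_T), the joint probability of
  having **departed the healthy eGFR distribution** since the previous
  visit — the per-interval outcome of the time-updated risk-factor
  analyses.

Parameters (log-rates, μ_H, log σ_H, δ, logit π_U) are estimated by
pooled maximum likelihood with multi-start L-BFGS-B. Downstream the
package provides: the two-consecutive-measures CKD event rule,
Kaplan–Meier CKD-free survival, exact-Poisson incidence rates, Cox
proportional hazards with time-updated covariates (counting-process
layout), and a **fractional-logit** (quasi-binomial, cluster-robust)
regression of the departure probabilities on time-updated exposures, with
intervals censored when the previous-visit γ exceeds 50%. A synthetic
cohort generator with the study's design (two recruitment phases,
imperfect attendance, exposure-scaled transition intensities) makes every
stage testable and supports recovery experiments.

## Worked example

```python
from nephrohmm import (SyntheticConfig, simulate_cohort, trajectories_from_table,
                       fit_hmm, FitConfig, posterior_states, classify_states)

cfg = SyntheticConfig(seed=42)          # two cohorts, 351 + 420 participants
sim = simulate_cohort(cfg)
trajs = trajectories_from_table(sim.visits)
fit = fit_hmm(trajs, FitConfig(seed=42))
p = fit.params
print(f"healthy eGFR ~ N({p.mu_H:.1f}, {p.sigma_H:.1f}^2), pregnancy shift +{p.delta_preg:.1f}")

post = posterior_states(trajs[0], fit.params)
print([round(g, 3) for g in post.gamma])
```

prints

```
healthy eGFR ~ N(123.8, 10.6^2), pregnancy shift +14.3
[0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.003, 0.014]
```

i.e. the fit recovers the generating healthy-emission mean/SD
(123.8 / 10.7) and pregnancy shift (truth 15.8), and the first
participant stays confidently healthy at every attended visit (all
smoothed unhealthy-state probabilities near zero, no probable-departure
interval with ξ > 0.5).

The same analysis runs from the shell:

```bash
nephrohmm run-all --config cfg.yaml --out results/ --seed 42
```

writing the validated visit table, fitted parameters (JSON), per-visit
posteriors, survival/Kaplan–Meier/incidence tables, the per-exposure
odds-ratio screen, and a run manifest with a config hash and per-stage
row counts.

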