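# coxdiag

Age-related heterogeneity diagnostics for Cox proportional-hazards models
in prospective cohort studies.

## The problem

Time-to-event analyses of birth cohorts — for example, children followed
from birth for the onset of islet autoimmunity, the preclinical phase of
type 1 diabetes — usually rely on the Cox model

    h(t | x) = h0(t) · exp(β x),

which assumes a covariate's hazard ratio HR = exp(β) is constant over age.
When an exposure matters only at certain ages ("etiologic heterogeneity"),
β is really a function β(t), the proportional-hazards (PH) assumption
fails, and an association averaged over all ages can be attenuated to the
point of invisibility. `coxdiag` provides the three standard diagnostics
for detecting and modelling an age-varying hazard ratio, for both fixed and
time-varying (re-measured) covariates:

1. **Supremum test** — the observed cumulative score process
   U(t) = n^(-1/2) Σ_{t_k ≤ t} s_k (running sum of a covariate's Schoenfeld
   residuals) is compared against 1,000 multiplier-resampled null paths;
   the p-value is the fraction of simulated suprema ≥ the observed
   supremum.
2. **Scaled Schoenfeld residual (zph) test** — each event's residual,
   scaled by m·V̂ and offset by β̂, approximates β(t_event); a zero-slope
   score test against transformed event time gives per-covariate 1-df and
   global tests, with a local-linear smooth of β(t) and ±2·SE band.
3. **Restricted cubic spline (RCS) time interaction** — the model
   β(t) = θ₀ + θ₁t + Σ θⱼ bⱼ(t) with a k-knot restricted cubic basis
   (knots at the 5th/50th/95th percentiles of event ages for k = 3)
   fitted by partial likelihood, with hierarchical Wald tests —
   association (k df), nonconstancy (k−1 df, the PH test), nonlinearity
   (k−2 df) — AIC-based knot selection, and HR(t) curves
   exp(Δ·β̂(t)) with pointwise delta-method confidence bands.  Because the
   interaction basis is evaluated at each event time against the episodes
   then at risk, the construction extends directly to time-varying
   covariates on counting-process data.

Everything is built on a left-truncation-aware counting-process Cox engine
(Newton–Raphson, Breslow or Efron ties) written against the risk-set rule
`start < t ≤ stop`, so delayed entry, episode-split exposures and
time-interaction designs all share one verified code path.

A cohort simulator (`coxdiag.simulate`) emulates a visit-based birth
cohort — staggered entry between birth and age 8, visits at 9/15/24 months
then annually (with per-child timing variability), events recorded at the
first positive visit, left-censored cases flagged and excluded — and
drives the calibration, power and recovery studies in the test suite.

## Worked example

```python
from coxdiag import AssessmentConfig, run_assessment, named_scenario, simulate_cohort

subjects, _ = simulate_cohort(named_scenario("nhw-like", n_subjects=1500, seed=11))
cfg = AssessmentConfig(
    covariates=[{"name": "nhw"}],
    adjustment=["hla", "fdr"],
    report_ages=[2.0, 11.0],
    seed=11,
)
report = run_assessment(subjects, None, cfg)
print(report.to_table())
```

prints

```
covariate supremum P zph global P zph individual P RCS association P RCS nonconstant P RCS nonlinear P
      nhw      0.004       0.0166          0.00482            0.0396             0.016           0.389
```

The `nhw-like` scenario simulates a binary covariate whose log hazard
ratio declines linearly with age (harmful early, protective late).  All
three diagnostics flag the PH violation: the supremum p (0.004) and the
zph global/individual p-values (0.017 / 0.005) are small, and the spline
hierarchy finds an association (p = 0.04) that is nonconstant in age
(p = 0.016) but not detectably nonlinear (p = 0.39) — i.e. a linear drift
in the log hazard ratio, which is exactly how the cohort was generated.
The fitted curve, with 3 knots placed at the event-age percentiles
(here 1.3, 4.1, 12.0 years), quantifies the reversal:

```
HR(age 2.0): 2.17 (95% CI 1.05, 4.46)
HR(age 11.0): 0.53 (95% CI 0.27, 1.03)
```

8 simulated subjects were already positive at their first visit
(left-censored onset) and were excluded before fitting.

The same pipeline is available from the shell:

```bash
coxdiag simulate --scenario nhw-like --seed 11 --out cohort/
coxdiag assess --subjects cohort/subjects.csv --covariate nhw --out report.json
coxdiag power --scenario null --test rcs_nonconstant --reps 200 --seed 1
```

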