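# Methods

## Data-generating model

Each simulated study observes `n` units at times `t = 1..T`. Unit `i` is
assigned to the treated group (`d_i = 1`) with probability `p_treat`;
treatment switches on for the whole treated group at a single time `t0`
(`p_t = 1{t ≥ t0}`). Outcomes follow

```
y_it = α₀ + α₁ d_i + ζ_t + λ_t x_it + γ p_t d_i + ε_it,   ε_it ~ N(0, σ_y²)
```

with time fixed effects `ζ_t`, a single covariate `x_it`, an effect schedule
`λ_t`, and a constant additive treatment effect `γ`. The covariate is either

- **time-invariant**: `x_i = μ_{d_i} + η_i`, `η_i ~ N(0, σ_x²)`, replicated
  across time (`μ_d = a0 + a1·d`); or
- **time-varying**: `x_it = a0 + a1 d_i + (b0 + b1 d_i) t
  + δ d_i p_t (t − t0 + 1) + η_it`, `η_it ~ N(0, σ_x²)` drawn independently
  per (unit, time).

`δ ≠ 0` means treatment itself shifts the treated group's covariate after
`t0`, linearly in elapsed posttreatment time — the covariate then acts as a
mediator.

Noise is homoskedastic Gaussian in both equations, independent across units,
times and groups, with no autocorrelation in the time-varying covariate
noise. These are the simplest processes consistent with a linear panel
model; an AR(1) covariate-noise option would be a natural extension (see
Limitations — the i.i.d. choice is load-bearing for the matching results).

## Confounding taxonomy and diagnostics

Parallel trends concerns untreated potential outcomes only, so diagnostics
evaluate the covariate's **untreated** mean path `m_d(t)` (`δ` suppressed).
The covariate-induced mean outcome gap between groups is

```
g(t) = λ_t · (m₁(t) − m₀(t)).
```

A constant `g` is absorbed by the group indicator `α₁` and is harmless; a
time-varying `g` violates parallel trends and biases the unadjusted
estimator. `violation_profile` computes `g` in closed form and flags
parallelism when the range of `g` is below 1e-10 (everything is closed-form,
so only floating-point noise is tolerated). `classify_confounding` returns
`treatment_affected_covariate` when `δ ≠ 0`, else `covariate_confounding`
when `g` varies, else `none`.

The population ATT averaged over posttreatment times is

```
ATT = γ + mean_{t ≥ t0} [ λ_t · δ · (t − t0 + 1) ],
```

i.e. exactly `γ` without mediation, and `γ` plus the average mediated
component otherwise. Averaging over posttreatment periods is the natural
scalarization when a single per-scenario truth is needed.

## The nine scenarios and default parameters

| id | covariate | group paths            | λ_t      | confounded |
|----|-----------|------------------------|----------|------------|
| 1  | invariant | means differ (μ₁ ≠ μ₀) | constant | no  |
| 2  | invariant | means differ           | varying  | yes |
| 3  | invariant | means equal            | varying  | no  |
| 4a | varying   | level-shifted, parallel| constant | no  |
| 4b | varying   | level-shifted, parallel| varying  | yes |
| 5a | varying   | diverge from baseline  | constant | yes |
| 5b | varying   | diverge from baseline  | varying  | yes |
| 6a | varying   | diverge post-t0 (δ≠0)  | constant | yes (mediator) |
| 6b | varying   | diverge post-t0 (δ≠0)  | varying  | yes (mediator) |

Scenario 4 keeps a nonzero group level difference (`a1 = 0.5`) with shared
slopes: with equal levels the time-varying effect in 4b would have nothing
to amplify and 4b would not be confounded. Scenario 6 starts both groups on
identical paths; only the posttreatment divergence distinguishes them.

Default numeric values (one place, overridable per call): `n = 800`,
`T = 10`, `t0 = 6`, `p_treat = 0.5`, `α₀ = 1`, `α₁ = 0.5`, `ζ_t = 0.1 t`,
`γ = 1`, `σ_y = 1`, `σ_x = 0.5`; constant `λ = 1`; time-varying
`λ_t = 0.5 + 0.2 t`; time-invariant means `μ₀ = 0`, `μ₁ = 1` (both 0 in
Scenario 3); time-varying paths `a0 = 0`, `b0 = 0.2`, `a1 = 0.5` where
levels differ, `b1 = 0.2` in Scenario 5, `δ = 0.3` in Scenario 6. These
magnitudes make the confounded cells' bias large relative to Monte Carlo
error at the default sample size while keeping every design well
conditioned. The effect schedule also accepts an arbitrary length-`T`
vector (`effect_kind="custom"`) as an escape hatch.

With these defaults the mediated ATTs are 1.9 (6a) and 3.01 (6b).

## Estimators

All three regressions include an intercept, `T − 1` time indicators, the
treated indicator and the treated×post interaction, whose coefficient is the
treatment-effect estimate:

- **simple** — nothing else (covariate ignored);
- **ca** — adds the covariate main effect `λ x_it`;
- **tva** — adds covariate-by-time interactions `λ_t x_it` (one coefficient
  per time point, no separate main effect).

Point estimates come from (weighted) least squares via `statsmodels`; rank
deficiency raises an explicit error rather than silently pinv-ing (e.g. a
constant covariate, or a time-invariant covariate with `σ_x = 0`, which
collapses onto the treated indicator).

Standard errors are CR1 cluster-robust, clustered on unit:

```
Var(β̂) = c · (X'WX)⁻¹ [ Σ_g s_g s_g' ] (X'WX)⁻¹,
s_g = X_g' W_g e_g,   c = G/(G−1) · (N−1)/(N−k).
```

With unit weights and singleton clusters this reduces to HC1. The
implementation is cross-checked in the test suite against `statsmodels`'
clustered covariance and against a hand-computed toy example, and achieves
93–97% null CI coverage in simulation.

**Matching** is 1:1 nearest-neighbor with replacement, treated → control,
Euclidean distance on matching vectors standardized coordinate-wise by the
pooled mean/SD over all units. The three matching vectors are: pretreatment
outcomes `(y_i1..y_i,t0−1)` (*level*), their first differences (*trend*),
and pretreatment covariate values (*cov*; for a time-invariant covariate the
pretreatment columns are identical, so this is equivalent to matching on the
scalar `x_i`). Distance ties break to the lowest control unit id for
determinism. Every treated unit is kept with weight 1; each matched control
enters once with a frequency weight equal to its multiplicity — identical
point estimates to row duplication (asserted in a test), with cleaner
clustering semantics (a reused control is one cluster). The matched sample
is then analyzed with the simple regression. Euclidean covariate distance
was chosen over a propensity-score distance as the transparent option; the
choice is confined to `match_units` if an alternative is wanted.

## Monte Carlo engine

`run_study(scenario, n_reps, seed)` draws replicate `k` from the independent
child stream `(seed, k)` of a `numpy` `SeedSequence` — deterministic, and
any replicate can be regenerated alone. Estimator failures on a replicate
exclude that replicate from that estimator's aggregate; more than 1%
exclusions aborts the study (in practice exclusions are zero at the default
sizes). Metrics per estimator: mean absolute percent bias
`|mean(γ̂) − ATT| / |ATT| × 100` (undefined for a zero ATT — the metric
raises, the study reports NaN), mean SE, RMSE, and the Monte Carlo SE of the
mean estimate `sd(γ̂)/√n_reps`, which calibrates all "unbiased within 3 MC
SEs" / "biased beyond 5 MC SEs" statements.

## What the generator does and does not emulate

The generator produces true panels (repeated measures on the same units),
exhaustively crossing the confounding mechanisms above. It does **not**
emulate: repeated cross-sections, unbalanced panels or attrition, covariate
measurement error, autocorrelated or heteroskedastic noise, staggered
adoption, nonlinear links, or heterogeneous treatment effects. Passing tests
therefore demonstrate estimator behavior under clean linear-Gaussian
conditions, not robustness to any of the above.

## Problem sizes used by the shipped checks

Acceptance-style studies run 150 replicates per scenario at the default
n = 800, T = 10 (the headline-target script uses 200 replicates); the
brute-force parallel-trends oracle simulates 10⁶ untreated units; CI
coverage uses 1000 replicates of a 200-unit, 4-period null panel. At these
sizes the full test suite completes in a few minutes on one core.

## Known limitations

- **Matching results are sensitive to the noise parameterization.** With
  i.i.d. noise and a group level offset (`α₁ ≠ 0`), nearest-neighbor
  matching on noisy pretreatment outcomes must bridge part of the offset by
  selecting favorable noise realizations, which revert after `t0` —
  regression to the mean. Under the defaults this makes `match_level`
  measurably biased even in unconfounded scenarios (1, 4a), and `match_cov`
  in 4a through the same mechanism in the covariate noise. With a persistent
  (unit-level) noise component, or `σ_y ≪` the matching signal, these biases
  shrink toward zero; the framework's defaults deliberately keep a single
  simple noise structure rather than tuning per cell, so matching
  conclusions should be read as conditional on it.
- **Scenario 6 mediation structure.** Because both groups share identical
  covariate paths before `t0` and the divergence is purely
  treatment-induced, parallel trends hold for untreated outcomes, and the
  *unadjusted* estimators (simple, and matching on pretreatment quantities)
  consistently estimate the total effect — which here *is* the ATT
  (direct + mediated). Covariate-adjusted estimators (CA, TVA) instead
  recover ≈ `γ`, the direct effect, and are therefore biased for the ATT.
  Under mediation structures where the pre-period paths also differ, or
  where the covariate feeds back on later outcomes, no estimator in this
  suite recovers the ATT; such structures are outside the current generator.
- Percent bias is undefined at a zero true ATT; use RMSE/absolute bias for
  null-effect designs.
- The CR1 small-sample correction is the conventional default but not
  second-order accurate; with very few clusters a wild-cluster bootstrap
  would be preferable and is not implemented.
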