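# Methods

## Model

Each subject *i* contributes a sequence of binary responses
y_{i,1..T_i} with covariates u_{i,t} ∈ ℝᵖ. The observation model is
Bernoulli with logistic link,

    y_it ~ Bern( σ(w_i' u_it + x_it) ),

and the latent decision criterion x follows a per-subject AR(1),

    x_it = b_i + a_i x_{i,t-1} + ε_it,   ε_it ~ N(0, σ²_i),
    b_i  = μ_{x,i} (1 − a_i).

Tying the intercept to the trajectory mean makes μ_{x,i} the subject's
habitual response bias and removes one redundant degree of freedom;
consequently a *constant* covariate column is not allowed (the criterion
mean already is the intercept), and the dataset readers enforce that.

Subject-level parameters are pooled through
w_i ~ N(μ_w, diag(σ²_w)), a_i ~ TruncNorm(μ_a, σ²_a, [0,1]),
σ²_i ~ IGa(α_σ², β_σ²) and μ_{x,i} ~ N(0, σ²_{μx}), with the shape
reparametrised as α_σ² = β_σ²/μ_σ² + 1 so that μ_σ² is the prior mean of
σ²_i and the shape/scale posteriors decorrelate.

Assumptions worth stating plainly: responses are conditionally
independent given the criterion path; the drift is first-order Markov
with stationary persistence in [0,1]; all covariate effects are constant
within a session; there is one uninterrupted session per subject (no
gap/multi-session handling).

## Initial-state convention

The first trial needs a prior for x_1. The package's default —
used consistently by the simulator, the Kalman filter, and every
conditional — is **around_mean**: x_1 ~ N(μ_{x,i}, σ²_i), i.e. a session
starts at the subject's habitual bias up to one innovation. A
**stationary** option (x_1 ~ N(μ_{x,i}, σ²_i/(1−a_i²))) is also
implemented.

The default matters. Under the standard validation conditions
(μ_a = 0.98, sd_a = 0.03 truncated to [0,1]) roughly 1% of simulated
subjects draw a_i > 0.999, where the stationary standard deviation
σ_i/√(1−a_i²) is ~8 log-odds units: such a session starts — and, with
persistence that high, stays — saturated, every response identical, and
the subject's weights unidentifiable. Starting sessions at the habitual
bias avoids this degenerate regime and matches the recovery behaviour
the method is known for. A technical side benefit: with the around_mean
convention the conditional of a_i is an exact truncated normal (x_1 does
not involve a_i), whereas under the stationary convention the
sqrt(1−a²)-dependent x_1 term is handled by an exact
Metropolis-within-Gibbs correction (truncated-normal independence
proposal, accept against the initial-state factor).

## Posterior inference

One blocked Gibbs sweep, in fixed order (order does not affect validity,
only reproducibility):

1. **ω_it ~ PG(1, w_i'u_it + x_it)** — Pólya-gamma auxiliaries, one per
   trial, which render the Bernoulli likelihood Gaussian in the log-odds
   with pseudo-observations z_it = κ_it/ω_it − w_i'u_it,
   κ_it = y_it − ½, and noise variance 1/ω_it. The sampler is the exact
   Devroye alternating-series rejection sampler for PG(1, c) (numba-
   compiled, ~10⁶ draws/s); a truncated sum-of-gammas generator is kept
   as an independent cross-check.
2. **x_{i,1:T} | rest** — exact joint draw by forward filtering /
   backward sampling over the pseudo-observations (O(T) per subject).
3. **w_i | rest** — conjugate multivariate normal; precision
   diag(1/σ²_w) + Σ_t ω_it u_it u_it'.
4. **a_i | rest** — truncated-normal conditional from the centred AR(1)
   transitions (exact under around_mean; MH-corrected under stationary).
5. **σ²_i | rest** — inverse-gamma with shape α_σ² + T/2 and scale
   β_σ² + ½[Σ residuals² + (x_1 − μ_{x,i})²].
6. **μ_{x,i} | rest** — conjugate normal (the mean enters every
   transition through b_i and the initial state).
7. **(μ_w, σ²_w, σ²_{μx}) | rest** — closed-form normal / inverse-gamma
   draws.
8. **(μ_a, σ²_a, μ_σ², β_σ²) | rest** — one-at-a-time random-walk MH
   with symmetric Gaussian proposals against the product of per-subject
   prior densities times the hyperprior; out-of-domain proposals are
   rejected and α_σ² is re-derived after every move.

Correctness of every piece is tested against independent oracles (dense
chain-Gaussian for the FFBS, grid integration for each scalar
conditional, closed-form PG moments), and the assembled sampler passes a
Geweke successive-conditional test — after each sweep the responses are
re-simulated from the current state, and the marginal distribution of
every parameter is compared to its prior (two-sample KS, family-wise
α = 0.01 over eleven statistics).

## Hyperpriors

Weakly informative and proper, all exposed in `HyperPriorConfig`:

| parameter | prior | default |
|---|---|---|
| μ_w (each) | Normal | N(0, 2²) |
| σ²_w (each) | Inverse-gamma | IGa(2, 1) |
| μ_a | Normal truncated to [0,1] | N(0.5, 1²) on [0,1] |
| σ²_a | Half-normal | scale 0.5 |
| μ_σ² | Half-normal | scale 1 |
| β_σ² | Half-normal | scale 2 |
| σ²_{μx} | Inverse-gamma | IGa(2, 0.5) |

Half-normals are used for the variance-role MH parameters because,
unlike vague inverse-gammas, they keep mass near zero where σ²_a
plausibly lives (a population sd of the persistence of 0.03 means
σ²_a ≈ 0.001).

Constraining the *location* μ_a to [0,1] is deliberate. When every a_i
clusters near the upper boundary, the truncated-normal likelihood is
nearly flat along a ridge on which (μ_a, σ_a) grow together beyond 1 —
a location of 2–3 with a matched scale describes boundary-clustered
values just as well. An unconstrained location follows that ridge and
its credible intervals exclude the generative value; restricting the
location to the persistence domain removes the ridge and restores
nominal coverage.

## Sampler defaults and initialisation

1000 iterations with 250 burn-in and no thinning; all configurable.
Initialisation is deterministic: per-subject ridge-stabilised logistic
fits give w_i and (clipped to ±2) μ_{x,i}; a_i = 0.9, σ²_i = 0.1,
trajectories flat at μ_{x,i}; group-level parameters from the moments of
those initial values. MH step sizes start at (0.01, 0.005, 0.05, 0.1)
and adapt every 20 sweeps during burn-in toward ~0.3 acceptance
(multiplicative updates, clipped to [10⁻⁴, 2]); steps are frozen at the
end of burn-in so the post-burn-in kernel satisfies detailed balance.

Point estimates reported by the results object are posterior means over
post-burn-in samples; intervals are central equal-tailed percentiles
(simplest well-defined choice; highest-density intervals are not
implemented). Recovery correlations are Pearson correlations between
generative values and posterior means, and trajectory recovery is the
per-subject correlation averaged over subjects, not the pooled
correlation over concatenated trials (pooling mixes in the well-recovered
between-subject bias spread and flatters the number by ~0.1).

## Degenerate fitting modes

`estimate_fluctuations=False` pins x_it ≡ μ_{x,i}, reducing the model to
logistic regression with a hierarchical random intercept (the
"fixed-criterion" fits of the confound analyses); μ_{x,i} then gets a
direct PG-augmented conjugate update. `fixed_a=c` clamps every subject's
persistence at c (e.g. 0.9995, the near-random-walk convention of
earlier criterion-tracking tools) while everything else is estimated.

## Synthetic data: what it emulates and what it does not

The generator draws subject parameters from the hierarchy, covariates
i.i.d. standard normal, and responses through the model itself. The
standard validation conditions (`HyperParams.reference()`) are
μ_w = (0, 0.2, −0.1), σ²_w = (1,1,1), μ_a = 0.98, sd_a = 0.03,
μ_σ² = 0.2, β_σ² = 0.5, sd_μx = 0.5, with p = 3 covariates. A separate
sequential simulator builds history-bias agents whose second covariate
is the signed previous response (2y_{t−1}−1, first trial 0, so a
positive weight means repetition), generated trial-by-trial because the
covariate depends on earlier responses. Covariates are re-drawn per
dataset; one master seed spawns independent per-subject substreams, so
changing N or T never correlates draws across subjects.

What the generator does **not** emulate — and therefore what passing
recovery tests do not certify about real data: reaction times; session
breaks and day-to-day non-stationarity; learning or fatigue trends in
the *weights*; stimulus autocorrelation or blocked designs; lapses and
finger errors; criterion dynamics other than AR(1) (e.g. discrete
strategy switches). On real data these would be model misspecification,
not estimation noise.

## Numerical choices

- Pseudo-observation Kalman form with observation variances 1/ω floored
  at 10⁻¹²; filtering variances floored at the same value.
- Truncated-normal sampling by inverse-CDF (exact even with the location
  many sd beyond a boundary, where rejection samplers stall); the
  uniform deviate is kept strictly inside (0,1) and draws are clipped a
  hair inside the truncation interval so a = 1 exactly cannot occur.
- Trajectory samples are stored as float32 (a 1000-iteration,
  50×500 run costs ~100 MB); parameters in float64.
- The logistic link is evaluated through `scipy.special.expit` / a
  log1p-form in numba code; no overflow for |z| ≤ 700.
- d′ uses the add-½-to-every-cell edge correction only when a cell is 0.

## Problem sizes used by the test suite and acceptance script

Published-scale runs (50 datasets × 50 subjects, up to 5000 trials,
~1 h/dataset on CPU in the original setting) are scaled to desk size;
this implementation fits 50×500×1000 iterations in ~20 s, which sets the
sizes below.

- Reference recovery: one dataset, 40 subjects × 500 trials, 600
  iterations (weights r ≈ .98–.99; a ≈ .7; σ² and μ_x dataset-dependent,
  ≈ .45–.99 and ≈ .4–.8 across seeds; trajectory r ≈ .81–.84).
- Long sessions: 20 subjects × 4000 trials, 500 iterations
  (a recovery ≈ .93–.96).
- Coverage: 5–6 datasets of 50 × 500, 500 iterations (92–95% of global
  95% intervals cover; β_σ² is the known hard case at 500 trials).
- Geweke: 2 subjects × 50 trials, 15 000 cycles, thinned by 40.
- Confound demos: 3 drift conditions × 6 subjects × 400 trials, both
  fitting modes, 350 iterations; d′ from 6 × 2000 trials per condition.
- Fixed-vs-free persistence: 10 subjects × 500 trials, both fits.

## Known limitations

Single-chain design: no cross-chain R-hat (mixing is monitored through
within-chain autocorrelation and MH acceptance). The trajectory-recovery
ceiling under the reference conditions is itself ≈ .82–.84 (smoothing
with the *true* subject parameters does no better), so reported
trajectory correlations saturate there. μ_x is weakly identified at
a → 1 (its likelihood information scales with (1−a)²), so its recovery
varies widely across dataset realisations at 500 trials. PG(b, c) is
implemented for integer b only (the model needs b = 1). Missing trials
within a session are not supported.
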