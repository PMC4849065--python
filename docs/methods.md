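# Methods

## Model

Each patient i carries latent random effects (U₀ᵢ, U₁ᵢ) ~ N(0, G) with
variances σ₀², σ₁² and correlation ρ, defining the latent trajectory
W₁ᵢ(t) = U₀ᵢ + U₁ᵢ t in outcome-score units. The observed outcome is

    Y_it = β₀ + β₁ Xᵢ + β_t t + W₁ᵢ(t) + Z_it,   Z_it ~ N(0, σ²) iid,

with Xᵢ the binary treatment arm. Dropout from cause l ∈ {1…K} has
cause-specific hazard λ₀⁽ˡ⁾(t)·exp(β₂⁽ˡ⁾Xᵢ + γ⁽ˡ⁾W₁ᵢ(t)), with λ₀⁽ˡ⁾
nonparametric (point masses at the observed cause-l event times; Breslow
convention, tied events share one increment, risk sets contain everyone
still under observation). Conditional on (U₀, U₁), the outcome and all event
processes are independent; the observed-data likelihood integrates the
product of the Gaussian outcome density, the cause-specific hazard/survival
terms, and the random-effect density over ℝ².

Two parameters named "β₂" in some presentations are kept strictly apart
here: `beta_time` (the time slope of the outcome model, per minute) and
`beta2_l` (the treatment log hazard ratio of cause l).

### Dropout taxonomy and survival coding

Causes: good prognosis, poor prognosis, unknown, unrelated, plus
completion. Completers are administratively censored at the final scheduled
visit; unrelated dropouts are treated as completely-random dropout and
censored at their dropout time. Unknown causes must be reclassified before
a K=2 fit: scenario 1 splits them evenly good/poor within each arm at
random (an odd remainder is assigned by a seeded coin flip; an explicit
allocation can be supplied, e.g. to reproduce a published split); scenario
2 assigns them all to poor prognosis. Under K=1 every dropout — including
unrelated — is by default one informative event process (the standard
joint model as usually applied, where "overall dropout" is the single
event); a flag censors unrelated dropouts instead.

Percentage conventions of the dropout summary: arm share of the total for
the baseline row; percent of the arm's baseline-assessed for completion and
overall dropout; percent of the arm's dropouts for each cause row.

## Estimation

### Linear mixed model

Full ML (not REML), so the likelihood is exactly the longitudinal factor of
the joint models and directly comparable. The marginal per-patient
covariance Σᵢ = ZᵢGZᵢᵀ + σ²I is evaluated in closed form with patients
grouped by visit pattern; fixed effects are profiled out by GLS and the
four variance parameters are optimised as (log σ₀², log σ₁², atanh ρ,
log σ²) by Nelder–Mead with a restart. Time is rescaled internally
(t′ = t/240 by default) because σ₁² per minute² sits ~5 orders of magnitude
below σ₀²; estimates are reported per minute. ML variance components at
this design (7 visits) carry a small negative finite-sample bias in the
slope variance and correlation (~5–10 % at 500 patients, verified against
an independent mixed-model implementation); mean parameters are unbiased to
Monte-Carlo precision.

### EM for the joint models

The latent (U₀, U₁) are the missing data. The 2-D integrals use tensor
Gauss–Hermite quadrature (default order 15 per dimension) centred and
scaled per patient at the mode/curvature of the Gaussian conditional
posterior given that patient's outcomes. Inside `fit_joint` this proposal
frame is frozen at initialisation; the EM then alternates

- **E-step**: posterior node weights ∝ quadrature weight × integrand, from
  which come the moments E[U], E[UUᵀ] and, for the M-step, posterior
  expectations of exp(γ(U₀+U₁s)) at every event time s and any γ;
- **M-step**: fixed effects and σ² from the expected-complete-data normal
  equations (closed form); G as the average posterior second moment; per
  cause, (β₂⁽ˡ⁾, γ⁽ˡ⁾) by Newton–Raphson with step-halving on the expected
  complete-data log-likelihood with the baseline profiled out, then the
  Breslow increments λ₀ₖ = dₖ / Σ_{risk set} E[exp(β₂x + γ(U₀+U₁sₖ))].

With the node frame fixed, the marginal likelihood being ascended is
exactly a finite-mixture likelihood on the node support, so every iteration
is a true EM step: the log-likelihood trace is monotone to machine rounding
(the test suite asserts violations below 1e-8). The frame is an
approximation choice, not an estimator change — `observed_loglik` and
`e_step` re-adapt to whatever parameters they are given, and the reported
`JointFit.loglik` is that re-adapted value; at order ≥ 9 the two agree to
well below 1e-3 on the problem sizes used here. Convergence requires both
the relative log-likelihood change below 1e-6 and the maximum absolute
parameter change (baseline increments included) below 1e-4, with a 500
iteration cap; non-convergence is flagged and the last iterate returned.

Initialisation: all-data LMM ML fit plus per-cause Cox–Breslow fits at
γ = 0 (a 1-D Newton on the partial likelihood — exactly the γ=0 special
case of the M-step). This makes γ=0-constrained fits equal the separate
analyses at iteration 0, an identity the tests exploit. A cause with zero
events contributes nothing and its parameters stay at initialisation,
which is also why the K=2 code path with one populated cause reproduces
the K=1 fit exactly.

Degenerate inputs: a posterior correlation update hitting |ρ| ≥ 0.999 is
clamped there (such fits are boundary-degenerate; the clamp keeps G
invertible at working precision). A patient whose likelihood contribution
underflows raises an explicit error rather than propagating -inf.

Reported quantities are invariant to the internal time rescaling: β₁ and
the hazard ratios trivially, and γ as well because W₁ is in score units
(the slope variance rescales, the product γW₁ does not); the suite asserts
this by fitting in raw minutes and in rescaled time.

### Bootstrap

Patient-level resampling with replacement, stratified by arm so every
replicate preserves the randomisation ratio (an unstratified mode exists).
Intervals are bias-corrected percentile without acceleration:
z₀ = Φ⁻¹(fraction of replicates strictly below the point estimate), bounds
at the Φ(2z₀ ± z_{α/2}) empirical quantiles (linear-interpolation order
statistics). All-identical replicates give a flagged degenerate interval;
if every replicate falls on one side of the point estimate (z₀ undefined,
typical at very small B) the replicate range is reported and flagged.
Replicates where the estimator fails are counted, never imputed; results
with >20 % failures are flagged unreliable. Joint-model replicates are
warm-started from the full-data fit — a speed choice that does not move
converged values. When scenario-1 analyses are bootstrapped, the random
allocation is redrawn inside each replicate by default (a frozen mode
reuses one allocation). The pipeline default is B = 1000; the test suite
uses B = 3–200 for runtime.

## Synthetic trials

The generator emulates the motivating 502-child acute-asthma trial: two
arms of 250, schedule {0, 20, 40, 60, 120, 180, 240} minutes,
administrative censoring at 240, bounded 0–9 severity score, ~20 % overall
dropout. Event times are drawn by exact inversion of the closed-form
piecewise cumulative hazard (on each piece the hazard is
λⱼ·e^{βx+γU₀}·e^{γU₁t}, integrable in closed form; patients whose total
hazard mass is exhausted never drop out). The earliest candidate across
causes before 240 minutes wins; outcomes are observed at scheduled times
strictly before the event (baseline always; completers at every visit);
informative dropouts are masked to "unknown" with probability 20/39,
matching the observed unknown share.

The shipped `magnetic_like_config` places its longitudinal and association
parameters near the published fitted magnitudes (treatment effect −0.19
score points; γ(good) = −0.8, γ(poor) = +0.2; HR(good) = 2, HR(poor) = 0.8)
— illustrative values, not ground truth — and its baseline hazard rates
were calibrated by simulation to the published per-arm cause mix, including
the arm imbalance of unrelated dropout (hazard ratio ≈ 2.05, matching the
41-vs-20 count). Good-prognosis dropout is concentrated after the 60-minute
treatment phase. `recovery_config` is the same trial structure with masking
off (recovery studies need the true cause observable) and the
poor-prognosis rate raised to ~5 % so both associations are identifiable
from a single trial. Scores are left unclipped by default because clipping
to [0, 9] breaks the Gaussian model the estimators assume; a flag enables
it for realism demonstrations. A generator-only extension allows the
association to differ by arm (`gamma_control`), producing truths outside
the fitted model class for misspecification studies.

What the generator does not emulate: intermittent (non-monotone) missed
visits, integer-valued scores, covariates beyond the arm, arm-specific
associations in the *fitted* models, and the particular real-data structure
that made the published competing-risks treatment effect ~15 % smaller than
the standard-joint one. On data generated from the model class itself both
estimators are consistent for β₁, so passing recovery tests demonstrate
correctness of the estimators, not that the two models must disagree on
real data the way they did in the motivating trial.

## Problem sizes and tolerances used by the test suite

Small-instance oracles (direct derivative-free maximisation of the same
quadrature likelihood) run at 6 patients / 3 visits, agreement 1e-3 in
log-likelihood; the γ=0 factorisation identity is checked to 1e-6; the
Cox M-step against an independent Breslow implementation to 1e-6.
Parameter recovery uses 100 replicate trials of 500 patients at quadrature
order 5 (order 5 agrees with order 9 to ~5 decimals on these posteriors),
asserting means within 3 Monte-Carlo SEs; hazard ratios are assessed on
the log scale, where the estimator is asymptotically unbiased. Bootstrap
coverage uses 200 outer replicates at n = 200, B = 200. Directional checks
run over 20 seeded trials.
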