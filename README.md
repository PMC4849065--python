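# jmdropout

Joint modelling of longitudinal trial outcomes and informative dropout with
competing causes — for trial statisticians running sensitivity analyses when
patients leave a trial for reasons related to how they are doing.

## The problem

In trials with repeated outcome measurements (the motivating case is an
acute-asthma trial scoring children 0–9 every 20–60 minutes for four hours),
patients drop out early — some because they improved and were discharged
(*good prognosis*), some because they worsened and needed escalated care
(*poor prognosis*), some for unrecorded reasons, and some for reasons
unrelated to their health. The first three mechanisms make the missingness
non-ignorable: a complete-case mixed model, or any analysis that treats
dropout as independent censoring, can bias the estimated treatment effect.

## The model

The outcome follows a linear mixed model with patient-level random intercept
and slope,

    Y_it = β₀ + β₁ X_i + β_t t + W₁ᵢ(t) + Z_it,      W₁ᵢ(t) = U₀ᵢ + U₁ᵢ t,

with (U₀, U₁) bivariate normal and Z iid N(0, σ²). Each dropout cause
l = 1…K follows a cause-specific semi-parametric proportional-hazards model
sharing the same latent process:

    λ⁽ˡ⁾(t | X, W₁) = λ₀⁽ˡ⁾(t) · exp( β₂⁽ˡ⁾ X + γ⁽ˡ⁾ W₁(t) ).

γ⁽ˡ⁾ measures how strongly a patient's latent trajectory drives cause-l
dropout (γ < 0: dropping out goes with *low* scores), and exp(β₂⁽ˡ⁾) is the
treatment hazard ratio for that cause. K=1 is the standard joint model
(all-cause informative dropout); K=2 separates good- and poor-prognosis
dropout, with unrelated dropout independently censored. Estimation maximises
the joint likelihood by EM over (U₀, U₁) with adaptive Gauss–Hermite
quadrature and nonparametric (Breslow) baseline hazards; confidence
intervals come from the bias-corrected percentile bootstrap over patients.

The sensitivity analysis handles unknown-cause dropouts by reclassification:
**scenario 1** splits them evenly between good and poor prognosis at random;
**scenario 2** (worst case) assigns them all to poor prognosis.

## Worked example

```python
from jmdropout import (apply_scenario, fit_joint, generate_trial,
                       hazard_ratio, magnetic_like_config, summarize_dropout)

config = magnetic_like_config()          # 500-patient emulation trial
trial = generate_trial(config, seed=5)
print(summarize_dropout(trial).table())

fit1 = fit_joint(trial, K=1)             # standard joint model
scen1 = apply_scenario(trial, scenario=1, seed=15)
fit2 = fit_joint(scen1, K=2)             # competing-risks joint model
print(f"standard joint:  beta1 = {fit1.params.lmm.beta1:.3f}, "
      f"gamma = {fit1.params.causes[0].gamma:.3f}")
print(f"competing risks: beta1 = {fit2.params.lmm.beta1:.3f}, "
      f"HR(good) = {hazard_ratio(fit2, 1):.3f}, "
      f"gamma(good) = {fit2.params.causes[0].gamma:.3f}")
```

Output:

```
                     active     control       total
baseline         250 (50.0)  250 (50.0)         500
completed        171 (68.4)  214 (85.6)  385 (77.0)
dropout           79 (31.6)   36 (14.4)  115 (23.0)
case1_good        10 (12.7)    5 (13.9)   15 (13.0)
case2_poor          1 (1.3)     1 (2.8)     2 (1.7)
case3_unknown     12 (15.2)    8 (22.2)   20 (17.4)
case4_unrelated   56 (70.9)   22 (61.1)   78 (67.8)
```

```
standard joint:  beta1 = -0.202, gamma = -0.399
competing risks: beta1 = -0.200, HR(good) = 2.131, gamma(good) = -0.916
```

Reading: the treatment lowers the severity score by ~0.2 points at any
time; good-prognosis dropout is about twice as frequent under active
treatment (HR ≈ 2) and strongly associated with *lower* latent scores
(γ < 0) — patients leave early because they are doing well, and ignoring
that would misread the treatment effect.

The same sequence — dropout summary, complete-case mixed model, standard
joint model, both reclassification scenarios, bootstrap CIs — runs end to
end with `jmdropout run --config analysis.yaml` (see `jmdropout --help`).

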