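"""EM joint estimator: likelihood oracles, E/M-step correctness, fit
properties (monotonicity, reduction, equivalences, rescaling invariance)."""

import copy
import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import optimize

from jmdropout.joint_em import (
    BaselineHazard,
    CauseParams,
    CompetingJointParams,
    EmConfig,
    e_step,
    fit_joint,
    hazard_ratio,
    m_step,
    observed_loglik,
)
from jmdropout.mixed_model import LmmParams, fit_lmm, marginal_loglik
from jmdropout.synthetic_trial import generate_trial, magnetic_like_config, recovery_config
from jmdropout.trial_data import Cause, to_survival_records

FAST = EmConfig(quad_order=9, max_iter=300)


def _tiny_trial(n_per_arm=10, seed=5, schedule=(0.0, 60.0, 120.0, 240.0)):
    cfg = recovery_config(n_per_arm=n_per_arm, schedule=tuple(schedule))
    return generate_trial(cfg, seed)


def _cox_loglik(beta2, baseline, survival, status_code):
    """Full Breslow-parameterised Cox log-likelihood, direct from the formula."""
    lam = dict(zip(baseline.times, baseline.increments))
    ll = 0.0
    for s in survival:
        if s.status == status_code:
            ll += math.log(lam[s.time]) + beta2 * s.arm
        ll -= sum(v for t, v in lam.items() if t <= s.time) * math.exp(beta2 * s.arm)
    return ll


class TestObservedLoglik:
    def test_factorises_at_gamma_zero(self):
        """With no association the joint likelihood is the LMM marginal plus
        the Breslow-parameterised Cox likelihood, exactly."""
        d = _tiny_trial(n_per_arm=5)
        fit = fit_joint(d, K=1, config=FAST, gamma_fixed=0.0)
        survival = to_survival_records(d, K=1)
        p = fit.params
        ll_lmm = marginal_loglik(p.lmm, d)
        ll_cox = _cox_loglik(p.causes[0].beta2, p.causes[0].baseline, survival, 1)
        ll_joint = observed_loglik(p, d, survival, FAST)
        assert ll_joint == pytest.approx(ll_lmm + ll_cox, abs=1e-6)

    def test_quadrature_refinement_is_converged(self):
        d = _tiny_trial(n_per_arm=10, seed=9)
        fit = fit_joint(d, K=2, config=FAST)
        survival = to_survival_records(d, K=2)
        ll9 = observed_loglik(fit.params, d, survival, EmConfig(quad_order=9))
        ll25 = observed_loglik(fit.params, d, survival, EmConfig(quad_order=25))
        assert abs(ll9 - ll25) < 1e-4

    def test_no_events_reduces_to_lmm(self):
        cfg = magnetic_like_config(n_per_arm=8, causes=(), unrelated_rate=0.0)
        d = generate_trial(cfg, 2)
        survival = to_survival_records(d, K=1)
        p = CompetingJointParams(
            lmm=cfg.lmm,
            causes=(
                CauseParams(0.4, -0.7, BaselineHazard(1, (), ())),
            ),
        )
        ll = observed_loglik(p, d, survival, EmConfig(quad_order=11))
        assert ll == pytest.approx(marginal_loglik(cfg.lmm, d), abs=1e-8)


class TestEStep:
    def test_gamma_zero_moments_match_closed_form(self):
        d = _tiny_trial(n_per_arm=6, seed=3)
        fit = fit_joint(d, K=1, config=FAST, gamma_fixed=0.0)
        p = fit.params.lmm
        moms = e_step(fit.params, d, to_survival_records(d, K=1), FAST)
        G = p.G()
        Ginv = np.linalg.inv(G)
        for i, rec in enumerate(d.records):
            t = rec.times
            Z = np.column_stack([np.ones(t.size), t])
            C = np.linalg.inv(Z.T @ Z / p.sigma_sq + Ginv)
            r = rec.values - p.beta0 - p.beta1 * rec.arm - p.beta_time * t
            m = C @ (Z.T @ r) / p.sigma_sq
            assert moms.eu0[i] == pytest.approx(m[0], abs=1e-8)
            assert moms.eu1[i] == pytest.approx(m[1], abs=1e-8)
            assert moms.eu0_sq[i] == pytest.approx(C[0, 0] + m[0] ** 2, abs=1e-8)
            assert moms.eu0u1[i] == pytest.approx(C[0, 1] + m[0] * m[1], abs=1e-8)

    def test_population_mean_data_has_null_posterior_means(self):
        d = _tiny_trial(n_per_arm=4, seed=1)
        p = magnetic_like_config().lmm
        for rec in d.records:
            rec.measurements = [
                type(m)(rec.patient_id, m.time, p.beta0 + p.beta1 * rec.arm + p.beta_time * m.time)
                for m in rec.measurements
            ]
        params = CompetingJointParams(
            lmm=p, causes=(CauseParams(0.0, 0.0, BaselineHazard(1, (), ())),)
        )
        srec = [
            type(s)(s.patient_id, s.arm, s.time, 0)
            for s in to_survival_records(d, K=1)
        ]
        moms = e_step(params, d, srec, FAST)
        assert np.max(np.abs(moms.eu0)) < 1e-10
        assert np.max(np.abs(moms.eu1)) < 1e-12

    def test_second_moments_dominate_squared_means(self, small_trial):
        fit_params = fit_joint(small_trial, K=1, config=EmConfig(quad_order=5, max_iter=5)).params
        moms = e_step(fit_params, small_trial, to_survival_records(small_trial, K=1),
                      EmConfig(quad_order=9))
        assert np.all(moms.eu0_sq >= moms.eu0**2 - 1e-12)
        assert np.all(moms.eu1_sq >= moms.eu1**2 - 1e-15)


class TestMStep:
    def test_gamma_zero_update_is_breslow_cox(self):
        """With gamma fixed at 0 the cause update must match an independent
        Cox implementation with Breslow tie handling."""
        sksurv_lm = pytest.importorskip("sksurv.linear_model")
        d = _tiny_trial(n_per_arm=10, seed=13)
        survival = to_survival_records(d, K=1)
        lmm = fit_lmm(d).params
        init = CompetingJointParams(
            lmm=lmm, causes=(CauseParams(0.0, 0.0, BaselineHazard(1, (), ())),)
        )
        # build a starting parameter set whose baseline covers the event grid
        fit0 = fit_joint(d, K=1, config=FAST, gamma_fixed=0.0)
        moms = e_step(fit0.params, d, survival, FAST)
        updated = m_step(moms, d, survival, fit0.params, FAST, gamma_fixed=0.0)

        X = np.array([[s.arm] for s in survival], dtype=float)
        y = np.array(
            [(s.status == 1, s.time) for s in survival],
            dtype=[("event", bool), ("time", float)],
        )
        cox = sksurv_lm.CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12)
        cox.fit(X, y)
        assert updated.causes[0].beta2 == pytest.approx(cox.coef_[0], abs=1e-6)
        # Breslow baseline increments: steps of the estimated cumulative hazard
        chf = cox.cum_baseline_hazard_
        inc = np.diff(np.concatenate([[0.0], chf.y]))
        inc_at_events = {t: v for t, v in zip(chf.x, inc) if v > 0}
        ours = dict(zip(updated.causes[0].baseline.times, updated.causes[0].baseline.increments))
        assert set(ours) == set(inc_at_events)
        for t in ours:
            assert ours[t] == pytest.approx(inc_at_events[t], abs=1e-6)

    def test_baseline_increments_positive_risk_sets_decreasing(self):
        d = _tiny_trial(n_per_arm=12, seed=17)
        fit = fit_joint(d, K=2, config=FAST)
        for cp in fit.params.causes:
            inc = np.asarray(cp.baseline.increments)
            assert np.all(inc > 0)
            # increasing increments at fixed event count reflect shrinking risk sets
            survival = to_survival_records(d, K=2)
            n_at_risk = [
                sum(1 for s in survival if s.time >= t) for t in cp.baseline.times
            ]
            assert all(a >= b for a, b in zip(n_at_risk, n_at_risk[1:]))

    def test_m_step_is_stationary_at_the_fit(self, recovery_trial):
        fit = fit_joint(recovery_trial, K=2, config=EmConfig(quad_order=5, rel_tol=1e-9,
                                                             param_tol=1e-6, max_iter=600))
        survival = to_survival_records(recovery_trial, K=2)
        moms = e_step(fit.params, recovery_trial, survival, fit.config)
        updated = m_step(moms, recovery_trial, survival, fit.params, fit.config)
        assert updated.lmm.beta1 == pytest.approx(fit.params.lmm.beta1, abs=2e-4)
        for c_new, c_old in zip(updated.causes, fit.params.causes):
            assert c_new.beta2 == pytest.approx(c_old.beta2, abs=2e-3)
            assert c_new.gamma == pytest.approx(c_old.gamma, abs=2e-3)


class TestFitJoint:
    def test_em_matches_direct_maximisation_on_tiny_instance(self):
        d = _tiny_trial(n_per_arm=3, seed=23, schedule=(0.0, 120.0, 240.0))
        em = EmConfig(quad_order=9, rel_tol=1e-9, param_tol=1e-7, max_iter=2000)
        fit = fit_joint(d, K=1, config=em)
        survival = to_survival_records(d, K=1)
        grid = fit.params.causes[0].baseline.times

        def unpack(theta):
            lmm = LmmParams(
                beta0=theta[0], beta1=theta[1], beta_time=theta[2] / 240.0,
                sigma0_sq=math.exp(theta[3]), sigma1_sq=math.exp(theta[4]) / 240.0**2,
                rho=math.tanh(theta[5]), sigma_sq=math.exp(theta[6]),
            )
            lam = tuple(math.exp(v) for v in theta[9:])
            return CompetingJointParams(
                lmm=lmm,
                causes=(CauseParams(theta[7], theta[8], BaselineHazard(1, grid, lam)),),
            )

        def neg(theta):
            try:
                return -observed_loglik(unpack(theta), d, survival, em)
            except (ValueError, ArithmeticError):
                return 1e10

        i = fit.init
        x0 = np.array(
            [i.lmm.beta0, i.lmm.beta1, i.lmm.beta_time * 240.0,
             math.log(i.lmm.sigma0_sq), math.log(i.lmm.sigma1_sq * 240.0**2),
             math.atanh(i.lmm.rho), math.log(i.lmm.sigma_sq),
             i.causes[0].beta2, 0.0]
            + [math.log(v) for v in i.causes[0].baseline.increments]
        )
        best = np.inf
        for start in (x0, x0 + 0.1):
            r = optimize.minimize(neg, start, method="Nelder-Mead",
                                  options={"maxiter": 60000, "maxfev": 60000,
                                           "fatol": 1e-10, "xatol": 1e-8})
            best = min(best, r.fun)
        assert fit.loglik == pytest.approx(-best, abs=1e-3)

    def test_k1_reduction_identity(self):
        """Relabelling every informative dropout to one cause makes the K=2
        code path reproduce the K=1 fit exactly (same trace, same estimates)."""
        d = _tiny_trial(n_per_arm=15, seed=29)
        merged = d.copy()
        for rec in merged.records:
            if rec.cause in (Cause.POOR, Cause.UNKNOWN):
                rec.cause = Cause.GOOD
        f1 = fit_joint(merged, K=1, config=FAST, informative_unrelated=False)
        f2 = fit_joint(merged, K=2, config=FAST)
        assert np.allclose(f1.loglik_trace, f2.loglik_trace, atol=1e-10)
        assert f1.params.lmm == f2.params.lmm
        assert f1.params.causes[0] == f2.params.causes[0]
        assert len(f2.params.causes[1].baseline.times) == 0

    def test_em_monotone_trace(self, recovery_trial):
        for K in (1, 2):
            fit = fit_joint(recovery_trial, K=K, config=EmConfig(quad_order=5, max_iter=200))
            diffs = np.diff(fit.loglik_trace)
            assert diffs.min() > -1e-8

    def test_gamma_fixed_zero_equals_separate_fits(self):
        cfg = recovery_config(n_per_arm=60)
        causes = tuple(replace(c, gamma=0.0, gamma_control=None) for c in cfg.causes)
        d = generate_trial(replace(cfg, causes=causes), seed=31)
        fit = fit_joint(d, K=2, config=FAST, gamma_fixed=0.0)
        lmm = fit_lmm(d)
        assert fit.params.lmm.beta1 == pytest.approx(lmm.params.beta1, abs=1e-4)
        assert fit.params.lmm.sigma_sq == pytest.approx(lmm.params.sigma_sq, abs=1e-4)
        # the cause updates with gamma=0 are plain Cox fits; the initialiser
        # already is one, so EM must not move it
        assert fit.params.causes[0].beta2 == pytest.approx(
            fit.init.causes[0].beta2, abs=1e-6
        )

    def test_null_association_estimates_near_zero(self):
        cfg = recovery_config(n_per_arm=250)
        causes = tuple(replace(c, gamma=0.0, gamma_control=None) for c in cfg.causes)
        d = generate_trial(replace(cfg, causes=causes), seed=37)
        fit = fit_joint(d, K=2, config=EmConfig(quad_order=5, max_iter=300))
        lmm = fit_lmm(d)
        for cp in fit.params.causes:
            assert abs(cp.gamma) < 0.5  # ~2-3 SD at these event counts
        assert fit.params.lmm.beta1 == pytest.approx(lmm.params.beta1, abs=0.05)

    def test_time_rescaling_invariance(self):
        d = _tiny_trial(n_per_arm=12, seed=41)
        f_scaled = fit_joint(d, K=1, config=EmConfig(quad_order=9, time_scale=240.0))
        f_minutes = fit_joint(d, K=1, config=EmConfig(quad_order=9, time_scale=1.0))
        assert f_minutes.params.lmm.beta1 == pytest.approx(
            f_scaled.params.lmm.beta1, abs=1e-5
        )
        assert f_minutes.params.causes[0].beta2 == pytest.approx(
            f_scaled.params.causes[0].beta2, abs=1e-4
        )
        # W1 is in score units, so gamma does not rescale with time
        assert f_minutes.params.causes[0].gamma == pytest.approx(
            f_scaled.params.causes[0].gamma, abs=1e-4
        )

    def test_hazard_ratio_arithmetic(self, recovery_trial):
        fit = fit_joint(recovery_trial, K=1, config=EmConfig(quad_order=5, max_iter=3))
        p = fit.params
        obj = copy.deepcopy(fit)
        obj.params = CompetingJointParams(
            lmm=p.lmm,
            causes=(replace(p.causes[0], beta2=0.0),),
        )
        assert hazard_ratio(obj, 1) == 1.0
        obj.params = CompetingJointParams(
            lmm=p.lmm, causes=(replace(p.causes[0], beta2=math.log(2.0)),)
        )
        assert hazard_ratio(obj, 1) == pytest.approx(2.0)
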