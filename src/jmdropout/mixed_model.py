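"""Maximum-likelihood linear mixed model with random intercept and slope.

The outcome of patient i at time t is modelled as

    Y_it = beta0 + beta1 * X_i + beta_time * t + U0_i + U1_i * t + Z_it

with (U0, U1) bivariate normal (variances sigma0^2, sigma1^2, correlation
rho) and iid measurement error Z ~ N(0, sigma^2).  Marginally, each patient's
outcome vector is Gaussian with covariance Sigma_i = Z_i G Z_i' + sigma^2 I,
where Z_i = [1, t] is the random-effect design.  Estimation is full ML (not
REML) so the likelihood is directly comparable with, and initialises, the
joint longitudinal-dropout fits.

Numerics: time is rescaled internally (t' = t / time_scale) because the slope
variance per minute^2 is several orders below the intercept variance; the
optimiser works on (log-variances, atanh(rho)) with the fixed effects
profiled out by generalised least squares, and estimates are reported back on
the per-minute scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .trial_data import Cause, TrialDataset

__all__ = ["LmmParams", "LmmFit", "fit_lmm", "predict_mean", "marginal_loglik"]


@dataclass(frozen=True)
class LmmParams:
    """Parameters of the random-intercept/random-slope Gaussian model.

    ``beta1`` is the treatment effect in score units — the difference in
    expected outcome between arms at any time.  ``beta_time`` and the slope
    variance are on the per-minute scale.
    """

    beta0: float
    beta1: float
    beta_time: float
    sigma0_sq: float
    sigma1_sq: float
    rho: float
    sigma_sq: float

    def validate(self) -> None:
        if self.sigma0_sq <= 0 or self.sigma1_sq <= 0 or self.sigma_sq <= 0:
            raise ValueError("variance parameters must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")

    def G(self) -> np.ndarray:
        """2x2 random-effect covariance matrix."""
        s0 = math.sqrt(self.sigma0_sq)
        s1 = math.sqrt(self.sigma1_sq)
        off = self.rho * s0 * s1
        return np.array([[self.sigma0_sq, off], [off, self.sigma1_sq]])

    def rescaled(self, time_scale: float) -> "LmmParams":
        """Equivalent parameters when time is expressed in units of ``time_scale``."""
        return replace(
            self,
            beta_time=self.beta_time * time_scale,
            sigma1_sq=self.sigma1_sq * time_scale**2,
        )


@dataclass
class LmmFit:
    """Result of a mixed-model fit."""

    params: LmmParams
    loglik: float
    n_used: int
    n_obs: int
    converged: bool
    boundary: bool = False


def predict_mean(params: LmmParams, arm: int, t: float) -> float:
    """Population-mean outcome for the given arm at time t (minutes)."""
    return params.beta0 + params.beta1 * arm + params.beta_time * t


def _patient_arrays(dataset: TrialDataset, completers_only: bool):
    """Group patients by (times-pattern) so covariance factors are shared."""
    groups: dict[tuple, dict] = {}
    n_used = 0
    for rec in dataset.records:
        if completers_only and rec.cause is not Cause.COMPLETED:
            continue
        n_used += 1
        key = tuple(rec.times)
        g = groups.setdefault(key, {"y": [], "x": []})
        g["y"].append(rec.values)
        g["x"].append(rec.arm)
    out = []
    for times, g in groups.items():
        out.append(
            (
                np.asarray(times, dtype=float),
                np.vstack(g["y"]),
                np.asarray(g["x"], dtype=float),
            )
        )
    return out, n_used


def _profile_negloglik(theta, groups, return_beta=False):
    """Negative profile log-likelihood over the variance parameters.

    ``theta`` = (log s0^2, log s1^2, atanh rho, log sigma^2) on the rescaled
    time axis; beta is profiled out by GLS.
    """
    s0sq, s1sq = math.exp(theta[0]), math.exp(theta[1])
    rho = math.tanh(theta[2])
    ssq = math.exp(theta[3])
    off = rho * math.sqrt(s0sq * s1sq)
    G = np.array([[s0sq, off], [off, s1sq]])

    XtVX = np.zeros((3, 3))
    XtVy = np.zeros(3)
    pieces = []
    total_logdet = 0.0
    n_obs = 0
    for times, Y, x in groups:
        m = times.size
        Z = np.column_stack([np.ones(m), times])
        V = Z @ G @ Z.T + ssq * np.eye(m)
        L = np.linalg.cholesky(V)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        Vinv = np.linalg.inv(V)
        # design X_i = A + x_i * B with A = [1, 0, t], B = [0, 1, 0]
        A = np.column_stack([np.ones(m), np.zeros(m), times])
        B = np.column_stack([np.zeros(m), np.ones(m), np.zeros(m)])
        n_i = Y.shape[0]
        sx = x.sum()
        sx2 = (x**2).sum()
        AVA = A.T @ Vinv @ A
        AVB = A.T @ Vinv @ B
        BVB = B.T @ Vinv @ B
        XtVX += n_i * AVA + sx * (AVB + AVB.T) + sx2 * BVB
        YV = Y @ Vinv  # (n_i, m)
        XtVy += A.T @ YV.sum(axis=0) + B.T @ (x @ YV)
        total_logdet += n_i * logdet
        n_obs += n_i * m
        pieces.append((times, Y, x, Vinv, A, B))
    beta = np.linalg.solve(XtVX, XtVy)
    quad = 0.0
    for times, Y, x, Vinv, A, B in pieces:
        mu = A @ beta
        R = Y - mu[None, :] - np.outer(x, B @ beta)
        quad += np.einsum("ij,jk,ik->", R, Vinv, R)
    ll = -0.5 * (total_logdet + quad + n_obs * math.log(2.0 * math.pi))
    if return_beta:
        return ll, beta
    return -ll


def marginal_loglik(params: LmmParams, dataset: TrialDataset, completers_only: bool = False) -> float:
    """Closed-form marginal Gaussian log-likelihood at the given parameters."""
    params.validate()
    groups, _ = _patient_arrays(dataset, completers_only)
    ll = 0.0
    G = params.G()
    for times, Y, x in groups:
        m = times.size
        Z = np.column_stack([np.ones(m), times])
        V = Z @ G @ Z.T + params.sigma_sq * np.eye(m)
        L = np.linalg.cholesky(V)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        Vinv = np.linalg.inv(V)
        mu0 = params.beta0 + params.beta_time * times
        R = Y - mu0[None, :] - params.beta1 * x[:, None]
        quad = np.einsum("ij,jk,ik->", R, Vinv, R)
        ll += -0.5 * (Y.shape[0] * (logdet + m * math.log(2 * math.pi)) + quad)
    return float(ll)


def fit_lmm(
    dataset: TrialDataset,
    completers_only: bool = False,
    time_scale: float | None = None,
    max_iter: int = 500,
) -> LmmFit:
    """Fit the mixed model by full maximum likelihood.

    ``completers_only=True`` restricts to patients who completed the schedule
    (the complete-case analysis); otherwise all observed measurements of all
    patients contribute.
    """
    if time_scale is None:
        time_scale = dataset.admin_censor_time or 1.0
    groups_raw, n_used = _patient_arrays(dataset, completers_only)
    arms = {int(x) for _, _, xs in groups_raw for x in xs}
    if arms != {0, 1}:
        raise ValueError(
            "both treatment arms must be present (treatment effect inestimable)"
        )
    if n_used < 4:
        raise ValueError("need at least 2 patients per arm")
    groups = [(times / time_scale, Y, x) for times, Y, x in groups_raw]

    # moment-based starting values; slope variance scaled to the time range
    all_y = np.concatenate([Y.ravel() for _, Y, _ in groups])
    vtot = float(np.var(all_y)) or 1.0
    tmax = max(float(times.max()) for times, _, _ in groups if times.size) or 1.0
    x0 = np.array(
        [
            math.log(0.5 * vtot),
            math.log(0.1 * vtot / tmax**2 + 1e-300),
            0.0,
            math.log(0.5 * vtot),
        ]
    )
    res = optimize.minimize(
        _profile_negloglik,
        x0,
        args=(groups,),
        method="Nelder-Mead",
        options={"maxiter": max_iter * 4, "xatol": 1e-8, "fatol": 1e-10},
    )
    res2 = optimize.minimize(
        _profile_negloglik,
        res.x,
        args=(groups,),
        method="Nelder-Mead",
        options={"maxiter": max_iter * 4, "xatol": 1e-9, "fatol": 1e-11},
    )
    theta = res2.x if res2.fun <= res.fun else res.x
    ll, beta = _profile_negloglik(theta, groups, return_beta=True)
    s0sq, s1sq_sc = math.exp(theta[0]), math.exp(theta[1])
    rho = math.tanh(theta[2])
    ssq = math.exp(theta[3])
    params = LmmParams(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta_time=float(beta[2]) / time_scale,
        sigma0_sq=s0sq,
        sigma1_sq=s1sq_sc / time_scale**2,
        rho=rho,
        sigma_sq=ssq,
    )
    boundary = bool(
        min(theta[0], theta[1], theta[3]) < -18.0 or abs(rho) > 1.0 - 1e-6
    )
    n_obs = sum(Y.size for _, Y, _ in groups)
    return LmmFit(
        params=params,
        loglik=float(ll),
        n_used=n_used,
        n_obs=n_obs,
        converged=bool(res2.success or res.success) and not boundary,
        boundary=boundary,
    )
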