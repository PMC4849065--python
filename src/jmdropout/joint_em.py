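"""EM estimation of joint longitudinal / cause-specific dropout models.

The model couples the linear mixed outcome model

    Y_it = beta0 + beta1 X_i + beta_time t + W1_i(t) + Z_it,
    W1_i(t) = U0_i + U1_i t,

with K cause-specific semi-parametric proportional-hazards dropout processes
sharing the same latent process:

    lambda_l(t | X, W1) = lambda0_l(t) exp(beta2_l X + gamma_l W1(t)).

K=1 is the standard joint model with a single all-cause dropout process;
gamma_l measures how strongly the latent outcome trajectory drives cause-l
dropout, and exp(beta2_l) is the treatment hazard ratio for cause l adjusted
for that trajectory.  The baseline hazards are nonparametric, with mass only
at observed cause-l event times (Breslow construction, ties share one
increment).

Estimation maximises the observed-data likelihood

    L_i = int f(Y_i | u) [prod_l hazard_l(T_i | u)^{1(status=l)}]
              exp(-sum_l Lambda_l(T_i | u)) phi(u; G) du

by EM over the latent (U0, U1), with the 2-D integrals approximated by
tensor Gauss-Hermite quadrature centred and scaled per patient at the
mixed-model conditional posterior.  Inside :func:`fit_joint` the per-patient
quadrature frame is frozen at initialisation, which makes every EM iteration
an exact ascent step on the fixed-node objective: the log-likelihood trace
is monotone to machine precision.

Note on symbols: ``beta_time`` (the time slope of the outcome model) and
``beta2_l`` (the treatment log hazard ratio of cause l) are distinct
parameters that some presentations both write as "beta2"; the names here
keep them apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .mixed_model import LmmFit, LmmParams, fit_lmm
from .trial_data import SurvivalRecord, TrialDataset, to_survival_records

__all__ = [
    "BaselineHazard",
    "CauseParams",
    "CompetingJointParams",
    "PosteriorMoments",
    "JointFit",
    "EmConfig",
    "observed_loglik",
    "e_step",
    "m_step",
    "fit_joint",
    "hazard_ratio",
]


@dataclass(frozen=True)
class BaselineHazard:
    """Nonparametric baseline hazard: masses at sorted event times (minutes)."""

    cause: int
    times: tuple[float, ...]
    increments: tuple[float, ...]

    def __post_init__(self):
        if len(self.times) != len(self.increments):
            raise ValueError("times and increments must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("baseline times must be strictly increasing")
        if any(v < 0 for v in self.increments):
            raise ValueError("baseline increments must be non-negative")

    def cumulative(self, t: float) -> float:
        return float(sum(v for s, v in zip(self.times, self.increments) if s <= t))


@dataclass(frozen=True)
class CauseParams:
    """Cause-specific parameters: treatment log-HR, association, baseline."""

    beta2: float
    gamma: float
    baseline: BaselineHazard


@dataclass(frozen=True)
class CompetingJointParams:
    """Joint-model parameter set: mixed model plus K cause-specific hazards."""

    lmm: LmmParams
    causes: tuple[CauseParams, ...]

    @property
    def K(self) -> int:
        return len(self.causes)


@dataclass(frozen=True)
class EmConfig:
    """Numerical settings for the EM fit.

    ``quad_order`` is the Gauss-Hermite order per latent dimension (total
    nodes = order^2).  Convergence requires both the relative change in the
    observed-data log-likelihood below ``rel_tol`` and the maximum absolute
    parameter change (internal scale, baseline increments included) below
    ``param_tol``.  ``time_scale`` divides all times internally for
    conditioning; reported parameters are always per-minute.
    """

    quad_order: int = 15
    rel_tol: float = 1e-6
    param_tol: float = 1e-4
    max_iter: int = 500
    time_scale: float | None = None

    def __post_init__(self):
        if self.quad_order < 3:
            raise ValueError("quad_order must be >= 3")
        if self.rel_tol <= 0 or self.param_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class PosteriorMoments:
    """Per-patient posterior moments of (U0, U1) given the full observed data.

    Moments are on the per-minute scale for U1.  The object also carries the
    quadrature representation (nodes and normalised weights) that produced
    them, which the M-step consumes to evaluate posterior expectations of
    exp(gamma * W1) at arbitrary gamma.
    """

    patient_ids: list[str]
    eu0: np.ndarray
    eu1: np.ndarray
    eu0_sq: np.ndarray
    eu1_sq: np.ndarray
    eu0u1: np.ndarray
    loglik_contrib: np.ndarray
    _internal: dict = field(repr=False, default_factory=dict)

    @property
    def loglik(self) -> float:
        return float(self.loglik_contrib.sum())


@dataclass
class JointFit:
    """Converged joint-model fit with its likelihood trace."""

    params: CompetingJointParams
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    config: EmConfig
    init: CompetingJointParams | None = None
    lmm_fit: LmmFit | None = None


def hazard_ratio(fit: JointFit, cause: int) -> float:
    """Treatment hazard ratio exp(beta2_l) for 1-based cause index ``cause``."""
    return math.exp(fit.params.causes[cause - 1].beta2)


# ---------------------------------------------------------------------------
# Internal problem representation (times rescaled)


class _Problem:
    """Padded array view of the dataset + survival records, times / scale."""

    def __init__(
        self,
        dataset: TrialDataset,
        survival: Sequence[SurvivalRecord],
        scale: float,
        grids: Sequence[np.ndarray] | None = None,
        K: int | None = None,
    ):
        by_id = {s.patient_id: s for s in survival}
        ids = dataset.patient_ids
        if set(by_id) != set(ids):
            raise ValueError("survival records do not match dataset patients")
        n = len(ids)
        m = max(len(r.measurements) for r in dataset.records)
        self.ids = ids
        self.scale = scale
        self.n = n
        self.y = np.zeros((n, m))
        self.tmat = np.zeros((n, m))
        self.mask = np.zeros((n, m))
        self.x = np.zeros(n)
        self.T = np.zeros(n)
        self.status = np.zeros(n, dtype=int)
        for i, rec in enumerate(dataset.records):
            k = len(rec.measurements)
            self.y[i, :k] = rec.values
            self.tmat[i, :k] = rec.times / scale
            self.mask[i, :k] = 1.0
            self.x[i] = rec.arm
            s = by_id[rec.patient_id]
            self.T[i] = s.time / scale
            self.status[i] = s.status
        self.nobs = self.mask.sum(axis=1)
        self.N = float(self.nobs.sum())
        self.K = K if K is not None else (int(self.status.max()) if n else 1)
        if grids is None:
            grids = [
                np.unique(self.T[self.status == l + 1]) for l in range(self.K)
            ]
        self.grids = [np.asarray(g, dtype=float) for g in grids]
        self.d = []
        self.atrisk = []
        self.ev_idx = []  # per cause: (patient indices, grid index of event)
        for l in range(self.K):
            s_l = self.grids[l]
            self.atrisk.append((self.T[:, None] >= s_l[None, :] - 1e-12).astype(float))
            pats = np.flatnonzero(self.status == l + 1)
            kidx = np.empty(pats.size, dtype=int)
            for j, i in enumerate(pats):
                hits = np.flatnonzero(np.abs(s_l - self.T[i]) <= 1e-9 * max(1.0, abs(self.T[i])))
                if hits.size == 0:
                    raise ValueError(
                        f"no baseline mass at the event time of patient {ids[i]!r} (cause {l + 1})"
                    )
                kidx[j] = hits[0]
            self.ev_idx.append((pats, kidx))
            d_l = np.zeros(s_l.size)
            for k in kidx:
                d_l[k] += 1.0
            self.d.append(d_l)
        # fixed-effect design cross-products (x_ij = (1, x_i, t_ij))
        msk = self.mask
        sx = (msk * self.x[:, None]).sum()
        st = (msk * self.tmat).sum()
        sxt = (msk * self.x[:, None] * self.tmat).sum()
        st2 = (msk * self.tmat**2).sum()
        self.XtX = np.array([[self.N, sx, st], [sx, sx, sxt], [st, sxt, st2]])


def _scaled_lmm(lmm: LmmParams, scale: float) -> LmmParams:
    return lmm.rescaled(scale)


def _unscale_lmm(lmm_sc: LmmParams, scale: float) -> LmmParams:
    return replace(
        lmm_sc,
        beta_time=lmm_sc.beta_time / scale,
        sigma1_sq=lmm_sc.sigma1_sq / scale**2,
    )


class _Quadrature:
    """Per-patient adaptive Gauss-Hermite frame (nodes on the internal scale)."""

    def __init__(self, problem: _Problem, lmm_sc: LmmParams, order: int):
        z, w = np.polynomial.hermite.hermgauss(order)
        Z0, Z1 = np.meshgrid(z, z, indexing="ij")
        self.z = np.column_stack([Z0.ravel(), Z1.ravel()])  # (Q, 2)
        self.logw = (
            np.add.outer(np.log(w), np.log(w)).ravel() + (self.z**2).sum(axis=1)
        )
        G = lmm_sc.G()
        Ginv = np.linalg.inv(G)
        ssq = lmm_sc.sigma_sq
        msk, t = problem.mask, problem.tmat
        a = problem.nobs / ssq + Ginv[0, 0]
        b = (msk * t).sum(axis=1) / ssq + Ginv[0, 1]
        c = (msk * t**2).sum(axis=1) / ssq + Ginv[1, 1]
        det = a * c - b * b
        C00, C01, C11 = c / det, -b / det, a / det
        r = msk * (
            problem.y
            - lmm_sc.beta0
            - lmm_sc.beta1 * problem.x[:, None]
            - lmm_sc.beta_time * t
        )
        zr0 = r.sum(axis=1) / ssq
        zr1 = (r * t).sum(axis=1) / ssq
        m0 = C00 * zr0 + C01 * zr1
        m1 = C01 * zr0 + C11 * zr1
        L00 = np.sqrt(C00)
        L10 = C01 / L00
        L11 = np.sqrt(np.maximum(C11 - L10**2, 1e-300))
        s2 = math.sqrt(2.0)
        self.U0 = m0[:, None] + s2 * L00[:, None] * self.z[None, :, 0]
        self.U1 = (
            m1[:, None]
            + s2 * (L10[:, None] * self.z[None, :, 0] + L11[:, None] * self.z[None, :, 1])
        )
        self.logconst = np.log(2.0) + np.log(L00 * L11)  # log(2 det L)
        self._Mm_cache: dict[int, np.ndarray] = {}

    def node_w1(self, grid: np.ndarray, l: int) -> np.ndarray:
        """W1 = U0 + U1 * s at every (patient, grid time, node); cached per cause."""
        Mm = self._Mm_cache.get(l)
        if Mm is None:
            Mm = self.U0[:, None, :] + self.U1[:, None, :] * grid[None, :, None]
            self._Mm_cache[l] = Mm
        return Mm


def _internal_params(params: CompetingJointParams, problem: _Problem, strict: bool = True):
    """(lmm_scaled, [(beta2, gamma, lam on grid)]) checked against the grids.

    With ``strict=False`` (warm starts on resampled data) grid times missing
    from the supplied baseline get the mean available increment; the first
    M-step replaces them anyway.
    """
    lmm_sc = _scaled_lmm(params.lmm, problem.scale)
    causes = []
    for l, cp in enumerate(params.causes):
        times = np.asarray(cp.baseline.times, dtype=float) / problem.scale
        lam = np.asarray(cp.baseline.increments, dtype=float)
        grid = problem.grids[l]
        if times.size == grid.size and np.allclose(times, grid, rtol=0, atol=1e-9):
            lam_on_grid = lam
        else:
            # align: every grid (data) time must carry a mass; extra baseline
            # times are folded into the grid for the cumulative hazard
            idx = {round(float(t), 12): v for t, v in zip(times, lam)}
            fill = float(lam.mean()) if lam.size else 1.0 / max(problem.n, 1)
            lam_on_grid = np.empty(grid.size)
            for k, s in enumerate(grid):
                key = round(float(s), 12)
                if key in idx:
                    lam_on_grid[k] = idx[key]
                elif strict:
                    raise ValueError(
                        f"baseline hazard for cause {l + 1} lacks mass at an "
                        "observed event time"
                    )
                else:
                    lam_on_grid[k] = fill
        causes.append((cp.beta2, cp.gamma, lam_on_grid))
    return lmm_sc, causes


def _external_params(
    lmm_sc: LmmParams, causes, problem: _Problem
) -> CompetingJointParams:
    out = []
    for l, (b2, g, lam) in enumerate(causes):
        out.append(
            CauseParams(
                beta2=float(b2),
                gamma=float(g),
                baseline=BaselineHazard(
                    cause=l + 1,
                    times=tuple(float(s * problem.scale) for s in problem.grids[l]),
                    increments=tuple(float(v) for v in lam),
                ),
            )
        )
    return CompetingJointParams(lmm=_unscale_lmm(lmm_sc, problem.scale), causes=tuple(out))


def _log_integrand(problem: _Problem, quad: _Quadrature, lmm_sc: LmmParams, causes):
    """log h(u) at every node: longitudinal x survival x prior terms."""
    msk, t = problem.mask, problem.tmat
    r = msk * (
        problem.y - lmm_sc.beta0 - lmm_sc.beta1 * problem.x[:, None] - lmm_sc.beta_time * t
    )
    e = r[:, :, None] - msk[:, :, None] * (
        quad.U0[:, None, :] + quad.U1[:, None, :] * t[:, :, None]
    )
    ss = np.einsum("nmq,nm->nq", e**2, msk)
    ll = -0.5 * ss / lmm_sc.sigma_sq - 0.5 * problem.nobs[:, None] * math.log(
        2 * math.pi * lmm_sc.sigma_sq
    )
    G = lmm_sc.G()
    Ginv = np.linalg.inv(G)
    logdetG = math.log(np.linalg.det(G))
    q = (
        Ginv[0, 0] * quad.U0**2
        + 2 * Ginv[0, 1] * quad.U0 * quad.U1
        + Ginv[1, 1] * quad.U1**2
    )
    ll += -math.log(2 * math.pi) - 0.5 * logdetG - 0.5 * q
    w1T = quad.U0 + quad.U1 * problem.T[:, None]
    for l, (b2, g, lam) in enumerate(causes):
        s_l = problem.grids[l]
        if s_l.size == 0:
            continue
        Mm = quad.node_w1(s_l, l)
        with np.errstate(over="ignore", under="ignore"):
            Eg = np.exp(g * Mm)
        phi = np.exp(b2 * problem.x)
        cum = phi[:, None] * np.einsum("k,nk,nkq->nq", lam, problem.atrisk[l], Eg)
        ll -= cum
        pats, kidx = problem.ev_idx[l]
        if pats.size:
            with np.errstate(divide="ignore"):
                loglam = np.log(lam[kidx])
            ll[pats] += (
                loglam[:, None]
                + b2 * problem.x[pats, None]
                + g * w1T[pats]
            )
    return ll


def _posterior(problem: _Problem, quad: _Quadrature, lmm_sc: LmmParams, causes):
    """Per-patient log-likelihood contributions and normalised node weights."""
    logh = _log_integrand(problem, quad, lmm_sc, causes)
    logw = logh + quad.logw[None, :]
    lse = logsumexp(logw, axis=1)
    contrib = lse + quad.logconst
    if not np.all(np.isfinite(contrib)):
        bad = [problem.ids[i] for i in np.flatnonzero(~np.isfinite(contrib))]
        raise ArithmeticError(
            f"likelihood contribution underflowed for patients {bad[:5]}"
        )
    W = np.exp(logw - lse[:, None])
    return contrib, W


def _moments_from_weights(problem: _Problem, quad: _Quadrature, W, contrib):
    eu0 = (W * quad.U0).sum(axis=1)
    eu1s = (W * quad.U1).sum(axis=1)
    eu0_sq = (W * quad.U0**2).sum(axis=1)
    eu1_sqs = (W * quad.U1**2).sum(axis=1)
    eu0u1s = (W * quad.U0 * quad.U1).sum(axis=1)
    s = problem.scale
    return PosteriorMoments(
        patient_ids=list(problem.ids),
        eu0=eu0,
        eu1=eu1s / s,
        eu0_sq=eu0_sq,
        eu1_sq=eu1_sqs / s**2,
        eu0u1=eu0u1s / s,
        loglik_contrib=contrib,
        _internal={"problem": problem, "quad": quad, "W": W,
                   "eu1_scaled": eu1s, "eu1_sq_scaled": eu1_sqs,
                   "eu0u1_scaled": eu0u1s},
    )


# ---------------------------------------------------------------------------
# Public single-step operations


def _build(dataset, survival_records, K, config):
    config = config or EmConfig()
    scale = config.time_scale or dataset.admin_censor_time or 1.0
    if survival_records is None:
        survival_records = to_survival_records(dataset, K)
    problem = _Problem(dataset, survival_records, scale, K=K)
    return problem, config


def observed_loglik(
    params: CompetingJointParams,
    dataset: TrialDataset,
    survival_records: Sequence[SurvivalRecord] | None = None,
    config: EmConfig | None = None,
) -> float:
    """Gauss-Hermite approximation to the observed-data log-likelihood."""
    problem, config = _build(dataset, survival_records, params.K, config)
    lmm_sc, causes = _internal_params(params, problem)
    quad = _Quadrature(problem, lmm_sc, config.quad_order)
    contrib, _ = _posterior(problem, quad, lmm_sc, causes)
    return float(contrib.sum())


def e_step(
    params: CompetingJointParams,
    dataset: TrialDataset,
    survival_records: Sequence[SurvivalRecord] | None = None,
    config: EmConfig | None = None,
) -> PosteriorMoments:
    """Posterior moments of (U0, U1) given each patient's full observed data."""
    problem, config = _build(dataset, survival_records, params.K, config)
    lmm_sc, causes = _internal_params(params, problem)
    quad = _Quadrature(problem, lmm_sc, config.quad_order)
    contrib, W = _posterior(problem, quad, lmm_sc, causes)
    return _moments_from_weights(problem, quad, W, contrib)


def _update_longitudinal(problem: _Problem, quad, W, moms_scaled):
    eu0, eu1 = moms_scaled["eu0"], moms_scaled["eu1"]
    eu0_sq, eu1_sq, eu0u1 = (
        moms_scaled["eu0_sq"],
        moms_scaled["eu1_sq"],
        moms_scaled["eu0u1"],
    )
    msk, t = problem.mask, problem.tmat
    ytil = msk * (problem.y - eu0[:, None] - eu1[:, None] * t)
    rhs = np.array(
        [
            ytil.sum(),
            (ytil * problem.x[:, None]).sum(),
            (ytil * t).sum(),
        ]
    )
    beta = np.linalg.solve(problem.XtX, rhs)
    r = msk * (problem.y - beta[0] - beta[1] * problem.x[:, None] - beta[2] * t)
    mu_u = eu0[:, None] + eu1[:, None] * t
    su = eu0_sq[:, None] + 2 * t * eu0u1[:, None] + t**2 * eu1_sq[:, None]
    ssq = float((msk * (r**2 - 2 * r * mu_u + su)).sum() / problem.N)
    g00 = float(eu0_sq.mean())
    g11 = float(eu1_sq.mean())
    g01 = float(eu0u1.mean())
    rho = g01 / math.sqrt(g00 * g11)
    # keep G invertible at working precision; |rho| this close to 1 is a
    # degenerate (boundary) fit in any case
    rho = max(min(rho, 0.999), -0.999)
    return LmmParams(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta_time=float(beta[2]),
        sigma0_sq=g00,
        sigma1_sq=g11,
        rho=rho,
        sigma_sq=max(ssq, 1e-12),
    )


def _cause_objective(problem, quad, W, l, beta2, gamma, Mm, S_x, S_m):
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        Eg = np.exp(gamma * Mm)
        a = np.einsum("nq,nkq->nk", W, Eg)
        phi = np.exp(beta2 * problem.x)
        S0 = (problem.atrisk[l] * a * phi[:, None]).sum(axis=0)
    d = problem.d[l]
    with np.errstate(divide="ignore", invalid="ignore"):
        obj = beta2 * S_x + gamma * S_m - float((d * np.log(S0)).sum())
    return obj, S0, a, Eg, phi


def _update_cause(problem, quad, W, l, beta2, gamma, gamma_fixed, max_newton=50):
    """Newton-Raphson on the expected complete-data profile likelihood."""
    s_l = problem.grids[l]
    if s_l.size == 0:
        return beta2, gamma, np.zeros(0)
    Mm = quad.node_w1(s_l, l)
    pats, kidx = problem.ev_idx[l]
    S_x = float(problem.x[pats].sum())
    w1T = (W * (quad.U0 + quad.U1 * problem.T[:, None])).sum(axis=1)
    S_m = float(w1T[pats].sum())
    d = problem.d[l]
    free_gamma = gamma_fixed is None
    if not free_gamma:
        gamma = float(gamma_fixed)
    obj, S0, a, Eg, phi = _cause_objective(problem, quad, W, l, beta2, gamma, Mm, S_x, S_m)
    for _ in range(max_newton):
        atr = problem.atrisk[l]
        with np.errstate(over="ignore", under="ignore"):
            b = np.einsum("nq,nkq->nk", W, Mm * Eg)
            xphi = phi * problem.x
            S1b = (atr * a * xphi[:, None]).sum(axis=0)
            Sg = (atr * b * phi[:, None]).sum(axis=0)
        r1 = S1b / S0
        r2 = Sg / S0
        grad_b = S_x - float((d * r1).sum())
        grad_g = S_m - float((d * r2).sum())
        if free_gamma:
            with np.errstate(over="ignore", under="ignore"):
                c = np.einsum("nq,nkq->nk", W, Mm**2 * Eg)
                Sxg = (atr * b * xphi[:, None]).sum(axis=0)
                Sc = (atr * c * phi[:, None]).sum(axis=0)
            Hbb = -float((d * (r1 - r1**2)).sum())
            Hbg = -float((d * (Sxg / S0 - r1 * r2)).sum())
            Hgg = -float((d * (Sc / S0 - r2**2)).sum())
            H = np.array([[Hbb, Hbg], [Hbg, Hgg]])
            grad = np.array([grad_b, grad_g])
        else:
            Hbb = -float((d * (r1 - r1**2)).sum())
            H = np.array([[Hbb]])
            grad = np.array([grad_b])
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            step = grad  # fall back to gradient ascent direction
        if not np.all(np.isfinite(step)):
            step = np.sign(grad)
        # step-halving safeguard
        scale_step = 1.0
        for _ in range(40):
            b2_new = beta2 + scale_step * step[0]
            g_new = gamma + scale_step * step[1] if free_gamma else gamma
            obj_new, S0_new, a_new, Eg_new, phi_new = _cause_objective(
                problem, quad, W, l, b2_new, g_new, Mm, S_x, S_m
            )
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            scale_step *= 0.5
        else:
            break  # no ascent possible: keep current point
        moved = max(abs(b2_new - beta2), abs(g_new - gamma))
        beta2, gamma = float(b2_new), float(g_new)
        obj, S0, a, Eg, phi = obj_new, S0_new, a_new, Eg_new, phi_new
        if moved < 1e-10:
            break
    lam = d / S0
    return beta2, gamma, lam


def m_step(
    moments: PosteriorMoments,
    dataset: TrialDataset,
    survival_records: Sequence[SurvivalRecord] | None,
    params: CompetingJointParams,
    config: EmConfig | None = None,
    gamma_fixed: Sequence[float | None] | float | None = None,
) -> CompetingJointParams:
    """One M-step: closed-form longitudinal/covariance updates, Newton +
    Breslow updates per cause, from the node representation in ``moments``."""
    problem = moments._internal["problem"]
    quad = moments._internal["quad"]
    W = moments._internal["W"]
    moms_scaled = {
        "eu0": moments.eu0,
        "eu1": moments._internal["eu1_scaled"],
        "eu0_sq": moments.eu0_sq,
        "eu1_sq": moments._internal["eu1_sq_scaled"],
        "eu0u1": moments._internal["eu0u1_scaled"],
    }
    lmm_new = _update_longitudinal(problem, quad, W, moms_scaled)
    gf = _normalise_gamma_fixed(gamma_fixed, params.K)
    causes_new = []
    for l, cp in enumerate(params.causes):
        b2, g, lam = _update_cause(problem, quad, W, l, cp.beta2, cp.gamma, gf[l])
        causes_new.append((b2, g, lam))
    return _external_params(lmm_new, causes_new, problem)


def _normalise_gamma_fixed(gamma_fixed, K):
    if gamma_fixed is None:
        return [None] * K
    if np.isscalar(gamma_fixed):
        return [float(gamma_fixed)] * K
    out = list(gamma_fixed)
    if len(out) != K:
        raise ValueError("gamma_fixed must have one entry per cause")
    return out


# ---------------------------------------------------------------------------
# Cox-Breslow fit (the gamma = 0 special case; used for initialisation)


def _cox_breslow(problem: _Problem, l: int, max_iter: int = 60):
    """Cox PH fit for a single binary covariate with Breslow tie handling."""
    s_l = problem.grids[l]
    if s_l.size == 0:
        return 0.0, np.zeros(0)
    pats, _ = problem.ev_idx[l]
    S_x = float(problem.x[pats].sum())
    d = problem.d[l]
    atr = problem.atrisk[l]
    beta = 0.0
    for _ in range(max_iter):
        phi = np.exp(beta * problem.x)
        S0 = (atr * phi[:, None]).sum(axis=0)
        S1 = (atr * (phi * problem.x)[:, None]).sum(axis=0)
        r = S1 / S0
        grad = S_x - float((d * r).sum())
        hess = -float((d * (r - r**2)).sum())
        if hess >= -1e-300:
            break
        step = -grad / hess
        beta += step
        if abs(step) < 1e-12:
            break
    phi = np.exp(beta * problem.x)
    S0 = (atr * phi[:, None]).sum(axis=0)
    return float(beta), d / S0


# ---------------------------------------------------------------------------
# The full EM fit


def _param_vector(lmm_sc: LmmParams, causes) -> np.ndarray:
    parts = [
        np.array(
            [
                lmm_sc.beta0,
                lmm_sc.beta1,
                lmm_sc.beta_time,
                lmm_sc.sigma0_sq,
                lmm_sc.sigma1_sq,
                lmm_sc.rho,
                lmm_sc.sigma_sq,
            ]
        )
    ]
    for b2, g, lam in causes:
        parts.append(np.array([b2, g]))
        parts.append(np.asarray(lam))
    return np.concatenate(parts)


def fit_joint(
    dataset: TrialDataset,
    K: int,
    config: EmConfig | None = None,
    init: CompetingJointParams | None = None,
    informative_unrelated: bool | None = None,
    gamma_fixed: Sequence[float | None] | float | None = None,
) -> JointFit:
    """Fit the joint model with K competing dropout causes by EM.

    Initialisation defaults to the all-data mixed-model ML fit plus per-cause
    Cox-Breslow fits at gamma = 0.  ``gamma_fixed`` constrains association
    parameters (scalar applies to every cause; a sequence may mix floats and
    None); with all gammas fixed at 0 the likelihood factorises and the fit
    reproduces the separate longitudinal and Cox analyses.
    """
    config = config or EmConfig()
    survival = to_survival_records(dataset, K, informative_unrelated)
    scale = config.time_scale or dataset.admin_censor_time or 1.0
    problem = _Problem(dataset, survival, scale, K=K)
    gf = _normalise_gamma_fixed(gamma_fixed, K)

    lmm_fit = None
    if init is None:
        lmm_fit = fit_lmm(dataset, completers_only=False, time_scale=scale)
        causes0 = []
        for l in range(K):
            b2, lam = _cox_breslow(problem, l)
            g0 = gf[l] if gf[l] is not None else 0.0
            causes0.append((b2, float(g0), lam))
        init = _external_params(_scaled_lmm(lmm_fit.params, scale), causes0, problem)
    lmm_sc, causes = _internal_params(init, problem, strict=False)

    quad = _Quadrature(problem, lmm_sc, config.quad_order)  # frozen frame
    trace = []
    prev_ll = -np.inf
    prev_vec = _param_vector(lmm_sc, causes)
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        contrib, W = _posterior(problem, quad, lmm_sc, causes)
        ll = float(contrib.sum())
        trace.append(ll)
        vec = _param_vector(lmm_sc, causes)
        if (
            n_iter > 1
            and abs(ll - prev_ll) <= config.rel_tol * max(1.0, abs(ll))
            and np.max(np.abs(vec - prev_vec)) <= config.param_tol
        ):
            converged = True
            break
        prev_ll, prev_vec = ll, vec
        # M-step
        eu0 = (W * quad.U0).sum(axis=1)
        eu1 = (W * quad.U1).sum(axis=1)
        moms = {
            "eu0": eu0,
            "eu1": eu1,
            "eu0_sq": (W * quad.U0**2).sum(axis=1),
            "eu1_sq": (W * quad.U1**2).sum(axis=1),
            "eu0u1": (W * quad.U0 * quad.U1).sum(axis=1),
        }
        lmm_sc = _update_longitudinal(problem, quad, W, moms)
        causes = [
            _update_cause(problem, quad, W, l, b2, g, gf[l])
            for l, (b2, g, _) in enumerate(causes)
        ]
    params = _external_params(lmm_sc, causes, problem)
    final_ll = observed_loglik(params, dataset, survival, config)
    return JointFit(
        params=params,
        loglik=final_ll,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
        config=config,
        init=init,
        lmm_fit=lmm_fit,
    )
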