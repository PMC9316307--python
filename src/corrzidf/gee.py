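"""GEE solver for the two-part zero-inflated model.

Solves the estimating equations

    U_N(beta) = sum_i D_i V_i^{-1} (f_i - h_i) = 0,
    V_i = A_i^{1/2} R(alpha) A_i^{1/2},

by Fisher scoring with step halving, alternating each outer iteration with
a moment update of the working-correlation parameter ``alpha`` from the
current Pearson residuals.  Coefficient covariance comes from the plug-in
sandwich estimator, which is valid even when the working correlation is
misspecified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .panel import (FeaturePanel, MomentState, ParamVector, compute_moments,
                    jacobian, jacobian_count_only, response_functions)
from .correlation import (WorkingCorrelation, build_R, estimate_alpha,
                          max_feasible_alpha, pearson_residuals)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Solver tolerances and iteration limits."""

    tol: float = 1e-6          # convergence threshold on max|delta theta|
    alpha_tol: float = 1e-4    # convergence threshold on |delta alpha|
    max_iter: int = 200        # outer (beta, alpha) iterations
    max_halvings: int = 10     # step halvings per Fisher-scoring update
    max_step: float = 5.0      # trust-region cap on a single scoring step
    beta_box: float = 30.0     # coefficients clamped to +-box (separation guard)
    moment_tol: float = 1e-9   # convergence on fitted means (separation rays)
    alpha_damping: float = 0.5 # relaxation of the alpha update (stability)


@dataclass(frozen=True)
class FitResult:
    """Fitted coefficients, sandwich covariance and diagnostics for one feature.

    ``sigma_beta`` is on the per-estimate scale (asymptotic covariance of
    ``sqrt(N)(beta_hat - beta)`` divided by N), ordered (beta_u, beta_v).
    ``status`` is one of ``ok`` / ``no_zeros`` / ``all_zero`` /
    ``not_converged``.
    """

    theta_hat: ParamVector
    alpha_hat: float
    sigma_beta: np.ndarray
    n_iter: int
    converged: bool
    max_abs_update: float
    structure: str
    status: str = "ok"
    score_norm: float = np.nan   # ||U_N||_inf at the returned estimate

    @property
    def zero_part(self) -> bool:
        return self.theta_hat is not None and self.theta_hat.beta_u is not None

    @property
    def p_u(self) -> int:
        return 0 if self.theta_hat is None else self.theta_hat.p_u

    def beta_v_cov(self) -> np.ndarray:
        """Sandwich covariance block of the count-part coefficients."""
        return self.sigma_beta[self.p_u:, self.p_u:]


# ---------------------------------------------------------------------------
# stacking helpers (time-interleaved order: f1_i1, f2_i1, ..., f1_iM, f2_iM)

# Var(f1) = h1(1-h1) underflows once mu is large (h1 ~ exp(-mu)); the floor
# keeps V_i invertible while the matching ~0 residual and Jacobian entries
# leave the estimating equations unchanged.
VAR_FLOOR = 1e-10


def _stack_pair(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    N, M = x2.shape
    out = np.empty((N, 2 * M))
    out[:, 0::2] = x1
    out[:, 1::2] = x2
    return out


def _stacked_arrays(panel: FeaturePanel, theta: ParamVector,
                    moments: MomentState):
    """Return (S, D, a): stacked residual f - h, Jacobian, working variances."""
    f1, f2 = response_functions(panel)
    if theta.beta_u is None:
        S = f2 - moments.h2
        D = jacobian_count_only(panel, theta, moments)
        a = moments.a2
    else:
        S = _stack_pair(f1 - moments.h1, f2 - moments.h2)
        D = jacobian(panel, theta, moments)
        a = _stack_pair(moments.a1, moments.a2)
    return S, D, np.maximum(a, VAR_FLOOR)


def assemble_V(moments: MomentState, corr: WorkingCorrelation, i: int) -> np.ndarray:
    """Working covariance ``V_i = A_i^{1/2} R(alpha) A_i^{1/2}`` for subject ``i``.

    ``A_i`` is the diagonal of working variances in the interleaved order
    (a1_i1, a2_i1, ..., a1_iM, a2_iM), or (a2_i1, ..., a2_iM) for the
    count-only (single-component) case.
    """
    if corr.n_components == 2:
        a = _stack_pair(moments.a1[i:i + 1], moments.a2[i:i + 1])[0]
    else:
        a = moments.a2[i]
    s = np.sqrt(np.maximum(a, VAR_FLOOR))
    return corr.R * np.outer(s, s)


def _assemble_V_all(a: np.ndarray, corr: WorkingCorrelation) -> np.ndarray:
    """Batched ``V_i`` for all subjects: (N, cM, cM)."""
    s = np.sqrt(a)
    return corr.R[None, :, :] * s[:, :, None] * s[:, None, :]


def _score_and_info(panel, theta, corr, moments=None):
    """U_N(theta), information B_N = sum_i D_i V_i^{-1} D_i', and V^{-1}S pieces."""
    if moments is None:
        moments = compute_moments(panel, theta)
    S, D, a = _stacked_arrays(panel, theta, moments)
    V = _assemble_V_all(a, corr)
    try:
        VinvS = np.linalg.solve(V, S[:, :, None])[:, :, 0]
        VinvDt = np.linalg.solve(V, np.transpose(D, (0, 2, 1)))
    except np.linalg.LinAlgError:
        logger.warning("singular V_i; applying ridge repair")
        V = V + 1e-8 * np.eye(V.shape[1])[None]
        VinvS = np.linalg.solve(V, S[:, :, None])[:, :, 0]
        VinvDt = np.linalg.solve(V, np.transpose(D, (0, 2, 1)))
    U = np.einsum("npk,nk->p", D, VinvS)
    B = np.einsum("npk,nkq->pq", D, VinvDt)
    return U, B, moments


def gee_step(panel: FeaturePanel, theta: ParamVector,
             corr: WorkingCorrelation, config: FitConfig = FitConfig()) -> ParamVector:
    """One Fisher-scoring update of ``beta`` with step halving.

    The proposed step is ``B^{-1} U_N``; it is halved (up to
    ``config.max_halvings`` times) while the Euclidean norm of the
    estimating function fails to decrease.
    """
    U, B, _ = _score_and_info(panel, theta, corr)
    try:
        delta = np.linalg.solve(B, U)
    except np.linalg.LinAlgError:
        logger.warning("singular information matrix; using pseudo-inverse")
        delta = np.linalg.pinv(B) @ U
    big = np.max(np.abs(delta))
    if big > config.max_step:     # separation or a near-singular B can
        delta = delta * (config.max_step / big)  # propose absurd steps
    norm0 = float(np.linalg.norm(U))
    theta0 = theta.as_array()
    for _ in range(config.max_halvings + 1):
        cand = theta.replace_from_array(
            np.clip(theta0 + delta, -config.beta_box, config.beta_box))
        U_new, _, _ = _score_and_info(panel, cand, corr)
        if float(np.linalg.norm(U_new)) < norm0 or norm0 == 0.0:
            return cand
        delta = delta / 2.0
    return cand


def _irls(X: np.ndarray, z_init: np.ndarray, y: np.ndarray, kind: str,
          n_iter: int = 25, tol: float = 1e-8) -> np.ndarray:
    """Small IRLS for initial values: logistic (kind='logit') of y in {0,1}
    on X, or Poisson log-linear (kind='log') of y >= 0 on X."""
    from scipy.special import expit

    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = z_init
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        if kind == "logit":
            m = expit(eta)
            w = np.clip(m * (1 - m), 1e-10, None)
        else:
            m = np.exp(eta)
            w = np.clip(m, 1e-10, None)
        z = eta + (y - m) / w
        WX = X * w[:, None]
        try:
            new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(np.sqrt(w)[:, None] * X,
                                  np.sqrt(w) * z, rcond=None)[0]
        if not np.all(np.isfinite(new)):
            break
        done = np.max(np.abs(new - beta)) < tol
        beta = new
        if done:
            break
    return np.clip(beta, -25, 25)


def initial_params(panel: FeaturePanel, zero_part: bool = True) -> ParamVector:
    """Cheap starting values: a logistic fit of I(y=0) on U for ``beta_u``
    and a Poisson log-linear fit of y on V restricted to y > 0 cells for
    ``beta_v``."""
    y = panel.y.astype(float)
    pos = y.reshape(-1) > 0
    Vflat = panel.V.reshape(-1, panel.p_v)
    ybar = max(float(y.reshape(-1)[pos].mean()), 1e-2) if pos.any() else 1e-2
    if pos.sum() > panel.p_v:
        beta_v = _irls(Vflat[pos], np.log(ybar), y.reshape(-1)[pos], "log")
    else:
        beta_v = np.zeros(panel.p_v)
        beta_v[0] = np.log(ybar)
    if not zero_part:
        return ParamVector(None, beta_v)
    f1 = (y == 0).astype(float).reshape(-1)
    zbar = float(np.clip(f1.mean(), 1e-3, 1 - 1e-3))
    Uflat = panel.U.reshape(-1, panel.p_u)
    beta_u = _irls(Uflat, np.log(zbar / (1 - zbar)), f1, "logit")
    return ParamVector(beta_u, beta_v)


def sandwich(panel: FeaturePanel, fit: FitResult) -> np.ndarray:
    """Plug-in sandwich covariance at the fitted parameters.

    Computes ``Sigma_hat = B_hat^{-1} M_hat B_hat^{-T}`` with
    ``B_hat = (1/N) sum_i D_i V_i^{-1} D_i'`` and
    ``M_hat = (1/N) sum_i D_i V_i^{-1} S_i S_i' V_i^{-1} D_i'``, and returns
    the per-estimate covariance ``Sigma_hat / N`` (symmetrized).
    """
    theta = fit.theta_hat
    moments = compute_moments(panel, theta)
    c = 2 if fit.zero_part else 1
    a_work = min(fit.alpha_hat, max_feasible_alpha(fit.structure,
                                                   panel.n_times, c))
    corr = build_R(fit.structure, a_work, panel.n_times, n_components=c)
    S, D, a = _stacked_arrays(panel, theta, moments)
    V = _assemble_V_all(a, corr)
    VinvS = np.linalg.solve(V, S[:, :, None])[:, :, 0]
    VinvDt = np.linalg.solve(V, np.transpose(D, (0, 2, 1)))
    N = panel.n_subjects
    B = np.einsum("npk,nkq->pq", D, VinvDt) / N
    G = np.einsum("npk,nk->np", D, VinvS)    # per-subject score contributions
    meat = G.T @ G / N
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError:
        logger.warning("singular bread matrix B; using pseudo-inverse")
        Binv = np.linalg.pinv(B)
    Sigma = Binv @ meat @ Binv.T / N
    return (Sigma + Sigma.T) / 2.0


def fit_feature(panel: FeaturePanel, structure: str = "ar1",
                config: FitConfig = FitConfig()) -> FitResult:
    """Fit the two-part GEE model to one feature panel.

    Alternates one Fisher-scoring update of ``beta`` with a moment update
    of ``alpha`` until ``max|delta beta| < config.tol`` and
    ``|delta alpha| < config.alpha_tol``, or ``config.max_iter`` outer
    iterations.

    Degenerate inputs: an all-zero feature is not fit (status
    ``all_zero``); a feature without any zero count is fit with the zero
    part disabled (rho fixed at 0, count component only; status
    ``no_zeros``) since the mixture weight is then unidentifiable.
    """
    y = panel.y
    if np.all(y == 0):
        return FitResult(theta_hat=None, alpha_hat=np.nan, sigma_beta=None,
                         n_iter=0, converged=False, max_abs_update=np.nan,
                         structure=structure, status="all_zero")
    zero_part = bool(np.any(y == 0))
    M = panel.n_times
    c = 2 if zero_part else 1
    theta = initial_params(panel, zero_part=zero_part)
    alpha = 0.0
    corr = build_R(structure, alpha, M, n_components=c)
    converged = False
    d_theta = np.inf
    it = 0
    mom = compute_moments(panel, theta)
    for it in range(1, config.max_iter + 1):
        theta_new = gee_step(panel, theta, corr, config)
        d_theta = float(np.max(np.abs(theta_new.as_array() - theta.as_array())))
        mom_new = compute_moments(panel, theta_new)
        # under quasi-separation beta_u drifts along a clipped flat ray; the
        # estimating equations only identify the fitted means, so stalling
        # on the moment scale counts as convergence
        d_mom = max(float(np.max(np.abs(mom_new.h1 - mom.h1))),
                    float(np.max(np.abs(mom_new.h2 - mom.h2)
                                 / (1.0 + np.abs(mom.h2)))))
        if structure != "independence" and M >= 2:
            res = pearson_residuals(panel, theta_new, mom_new)
            est = estimate_alpha(structure, res)
            # relaxed update: the plain alternating scheme can cycle
            alpha_new = (1 - config.alpha_damping) * alpha + config.alpha_damping * est
        else:
            alpha_new = 0.0
        d_alpha = abs(alpha_new - alpha)
        theta, alpha, mom = theta_new, alpha_new, mom_new
        if d_alpha > 0:
            # the working matrix uses alpha shrunk into the PD-feasible cone;
            # alpha_hat itself remains the raw moment estimate
            a_work = min(alpha, max_feasible_alpha(structure, M, c))
            corr = build_R(structure, a_work, M, n_components=c)
        if (d_theta < config.tol or d_mom < config.moment_tol) \
                and d_alpha < config.alpha_tol:
            converged = True
            break
    U, _, _ = _score_and_info(panel, theta, corr)
    status = "no_zeros" if not zero_part else ("ok" if converged else "not_converged")
    if zero_part and not converged:
        logger.warning("feature did not converge after %d iterations "
                       "(max|delta|=%.3g)", it, d_theta)
    fit = FitResult(theta_hat=theta, alpha_hat=alpha, sigma_beta=None,
                    n_iter=it, converged=converged, max_abs_update=d_theta,
                    structure=structure, status=status,
                    score_norm=float(np.max(np.abs(U))))
    return replace(fit, sigma_beta=sandwich(panel, fit))
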