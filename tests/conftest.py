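"""Shared fixtures: synthetic panel factories and a direct independence solver.

The independence solver duplicates the estimating equations with purely
diagonal weighting (it never forms a working-correlation matrix) and is
used as an oracle for the independence-structure reduction.
"""

import numpy as np
import pytest
from scipy.special import expit

from corrzidf import FeaturePanel, ParamVector
from corrzidf.gee import FitConfig, initial_params
from corrzidf.panel import compute_moments, jacobian, response_functions
from corrzidf.simulate import zip_quantile


def make_design(N, M, x=None):
    """Design arrays (N, M, 2): intercept + a subject-level covariate."""
    if x is None:
        x = np.repeat([0.0, 1.0], N - N // 2)[:N]
    X = np.ones((N, M, 2))
    X[:, :, 1] = np.asarray(x)[:, None]
    return X


def make_zip_panel(rng, N, M, beta_u=(-1.0, 0.5), beta_v=(1.0, 0.3),
                   copula_rho=0.0, structure="ar1", x=None):
    """Balanced two-part ZIP panel; optional Gaussian-copula serial dependence."""
    X = make_design(N, M, x)
    rho = expit(np.einsum("nmp,p->nm", X, np.asarray(beta_u, float)))
    mu = np.exp(np.einsum("nmp,p->nm", X, np.asarray(beta_v, float)))
    if copula_rho > 0:
        lags = np.abs(np.subtract.outer(np.arange(M), np.arange(M)))
        S = (copula_rho ** lags.astype(float) if structure == "ar1"
             else np.where(lags > 0, copula_rho, 1.0))
        z = rng.standard_normal((N, M)) @ np.linalg.cholesky(S).T
        from scipy.stats import norm
        y = zip_quantile(norm.cdf(z), rho, mu)
    else:
        y = np.where(rng.random((N, M)) < rho, 0, rng.poisson(mu))
    return FeaturePanel(y=y, U=X, V=X, u_names=("intercept", "group"),
                        v_names=("intercept", "group"))


def fit_independence_direct(panel, tol=1e-6, max_iter=200, max_halvings=10):
    """Fisher scoring for the two-part GEE with diagonal (independence)
    weighting only — no correlation matrix is ever assembled.

    Returns (theta_hat, per-estimate sandwich covariance, n_iter).
    """
    f1, f2 = response_functions(panel)
    theta = initial_params(panel, zero_part=True)

    def score_info(th):
        mom = compute_moments(panel, th)
        D = jacobian(panel, th, mom)            # (N, p, 2M)
        r = np.empty_like(D[:, 0, :])
        r[:, 0::2] = (f1 - mom.h1) / mom.a1
        r[:, 1::2] = (f2 - mom.h2) / mom.a2
        w = np.empty_like(r)
        w[:, 0::2] = 1.0 / mom.a1
        w[:, 1::2] = 1.0 / mom.a2
        U = np.einsum("npk,nk->p", D, r)
        B = np.einsum("npk,nk,nqk->pq", D, w, D)
        return U, B, mom, D, r

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        U, B, _, _, _ = score_info(theta)
        delta = np.linalg.solve(B, U)
        norm0 = np.linalg.norm(U)
        t0 = theta.as_array()
        for _ in range(max_halvings + 1):
            cand = theta.replace_from_array(t0 + delta)
            U_new, _, _, _, _ = score_info(cand)
            if np.linalg.norm(U_new) < norm0 or norm0 == 0.0:
                break
            delta = delta / 2.0
        step = np.max(np.abs(cand.as_array() - t0))
        theta = cand
        if step < tol:
            break
    U, B, mom, D, r = score_info(theta)
    N = panel.n_subjects
    G = np.einsum("npk,nk->np", D, r)
    Bn = B / N
    meat = G.T @ G / N
    Binv = np.linalg.inv(Bn)
    cov = Binv @ meat @ Binv.T / N
    return theta, (cov + cov.T) / 2.0, n_iter


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def zip_panel_factory():
    return make_zip_panel


@pytest.fixture
def independence_oracle():
    return fit_independence_direct


@pytest.fixture
def small_panel(rng):
    return make_zip_panel(rng, N=40, M=5)
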