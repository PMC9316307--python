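"""Working correlation structures over a subject's stacked responses.

A subject contributes ``c`` response components per time point (``c = 2``
for the two-part model: zero indicator and count).  The working correlation
``R(alpha)`` over the ``cM``-vector is built from ``c x c`` blocks: identity
blocks ``I_c`` within a time point (no cross-component correlation at the
same time) and ``g(|j - l|, alpha) * J_c`` between time points ``j != l``,
with ``J_c`` the all-ones block and

* AR(1):        ``g(h, alpha) = alpha ** h``
* exchangeable: ``g(h, alpha) = alpha``
* independence: ``g = 0``.

``alpha`` is estimated by moment (Pearson-residual) estimators pooling the
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .panel import FeaturePanel, MomentState, ParamVector, compute_moments, response_functions

logger = logging.getLogger(__name__)

STRUCTURES = ("independence", "ar1", "exchangeable")

ALPHA_MAX = 0.99
LAMBDA_FLOOR = 0.01   # minimum eigenvalue of R(alpha) after PSD repair
_VAR_TOL = 1e-12


@dataclass(frozen=True)
class WorkingCorrelation:
    structure: str
    alpha: float
    M: int
    R: np.ndarray          # (c*M, c*M)
    n_components: int = 2
    ridge: float = 0.0     # PSD repair actually applied


@dataclass(frozen=True)
class ResidualSet:
    """Componentwise standardized residuals at the current parameter value.

    ``e1 = (f1 - h1) / sqrt(a1)``, ``e2 = (f2 - h2) / sqrt(a2)``; each is an
    (N, M) matrix.  ``e1`` is ``None`` for zero-part-disabled fits.
    """

    e1: np.ndarray
    e2: np.ndarray


def build_R(structure: str, alpha: float, M: int,
            n_components: int = 2) -> WorkingCorrelation:
    """Assemble ``R(alpha)`` for the given structure.

    ``alpha`` outside ``[0, ALPHA_MAX]`` is clamped with a warning.  If the
    assembled matrix is not positive definite (possible for exchangeable
    structures with large ``alpha`` since the ``J`` blocks couple the two
    components), a ridge ``eps * I`` is added, with ``eps`` doubling from
    1e-8 until a Cholesky factorization succeeds.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; expected one of {STRUCTURES}")
    if M < 1:
        raise ValueError("M must be >= 1")
    if not (0.0 <= alpha <= ALPHA_MAX):
        clamped = float(np.clip(alpha, 0.0, ALPHA_MAX))
        logger.warning("alpha=%g outside [0, %g); clamped to %g", alpha, ALPHA_MAX, clamped)
        alpha = clamped
    c = n_components
    lags = np.abs(np.subtract.outer(np.arange(M), np.arange(M)))
    if structure == "independence":
        C = np.zeros((M, M))
    elif structure == "ar1":
        C = np.where(lags > 0, float(alpha) ** lags, 0.0)
    else:  # exchangeable
        C = np.where(lags > 0, float(alpha), 0.0)
    R = np.kron(C, np.ones((c, c))) + np.eye(c * M)
    # The all-ones off-diagonal blocks make R indefinite for moderately
    # large alpha (the two components are uncorrelated within a time point
    # but alpha-correlated across, which is infeasible as a correlation
    # matrix once alpha is big).  Repair with the smallest ridge eps*I that
    # lifts the minimum eigenvalue to LAMBDA_FLOOR.  Two constraints: the
    # ridge must be continuous in alpha (a stepped ridge makes the
    # alternating beta/alpha updates cycle instead of converge) and must
    # leave R well conditioned (a barely-positive floor puts ~1/floor
    # weight on the near-null eigendirection of V and blows up the score).
    ridge = 0.0
    lam_min = float(np.linalg.eigvalsh(R)[0])
    if lam_min < LAMBDA_FLOOR:
        ridge = LAMBDA_FLOOR - lam_min
        R = R + ridge * np.eye(c * M)
        logger.debug("R(alpha=%g, %s, M=%d) not PD (lambda_min=%.3g); ridge %g",
                     alpha, structure, M, lam_min, ridge)
    np.linalg.cholesky(R)
    return WorkingCorrelation(structure=structure, alpha=float(alpha), M=M,
                              R=R, n_components=c, ridge=ridge)


@lru_cache(maxsize=256)
def max_feasible_alpha(structure: str, M: int, n_components: int = 2) -> float:
    """Largest ``alpha`` for which ``R(alpha)`` is positive definite
    (minimum eigenvalue >= LAMBDA_FLOOR) without repair.

    For a single component the AR(1)/exchangeable correlation is PD for
    any ``alpha < 1``; with two components the all-ones cross blocks cap
    the feasible range (about 1/3 for AR(1), ``1/2`` for exchangeable).
    The GEE solver shrinks the estimated ``alpha`` to this bound before
    assembling ``V_i``: a working matrix inside the feasible cone weights
    the data strictly better than a heavily ridge-repaired infeasible one.
    """
    if structure == "independence" or M < 2 or n_components == 1:
        return ALPHA_MAX
    lo, hi = 0.0, ALPHA_MAX
    c = n_components
    lags = np.abs(np.subtract.outer(np.arange(M), np.arange(M)))
    for _ in range(40):
        a = (lo + hi) / 2.0
        C = np.where(lags > 0, a ** lags.astype(float) if structure == "ar1" else a, 0.0)
        R = np.kron(C, np.ones((c, c))) + np.eye(c * M)
        if np.linalg.eigvalsh(R)[0] >= LAMBDA_FLOOR:
            lo = a
        else:
            hi = a
    return lo


def pearson_residuals(panel: FeaturePanel, theta: ParamVector,
                      moments: MomentState = None) -> ResidualSet:
    """Componentwise Pearson residuals of (f1, f2) at ``theta``.

    Cells whose working variance underflows machine tolerance are set to 0
    (degenerate cell) with a warning.
    """
    if moments is None:
        moments = compute_moments(panel, theta)
    f1, f2 = response_functions(panel)

    def _std(f, h, a):
        bad = a <= _VAR_TOL
        if np.any(bad):
            logger.warning("%d degenerate residual cells set to 0", int(bad.sum()))
        e = np.zeros_like(h)
        ok = ~bad
        e[ok] = (f[ok] - h[ok]) / np.sqrt(a[ok])
        return e

    e2 = _std(f2, moments.h2, moments.a2)
    if theta.beta_u is None:
        e1 = None
    else:
        e1 = _std(f1, moments.h1, moments.a1)
    return ResidualSet(e1=e1, e2=e2)


def _components(residuals: ResidualSet):
    return [e for e in (residuals.e1, residuals.e2) if e is not None]


def estimate_alpha_ar1(residuals: ResidualSet) -> float:
    """Lag-1 moment estimator of the AR(1) working correlation.

    ``alpha_hat = sum_i sum_{j<=M-1} sum_c e_cij e_ci,j+1 / (n_c (K - 2))``
    with ``K = N (M - 1)`` adjacent pairs per component and ``n_c`` the
    number of pooled components.  Clamped to ``[0, ALPHA_MAX]``; a
    non-positive denominator falls back to independence.
    """
    comps = _components(residuals)
    N, M = comps[0].shape
    if M < 2:
        raise ValueError("AR(1) alpha estimation requires M >= 2")
    K = N * (M - 1)
    denom = len(comps) * (K - 2)
    if denom <= 0:
        logger.warning("too few adjacent pairs (K=%d); falling back to independence", K)
        return 0.0
    num = sum(float(np.sum(e[:, :-1] * e[:, 1:])) for e in comps)
    return float(np.clip(num / denom, 0.0, ALPHA_MAX))


def estimate_alpha_exchangeable(residuals: ResidualSet) -> float:
    """Moment estimator of the exchangeable working correlation.

    Sums residual products over all ordered pairs ``j != l`` in each
    component: ``alpha_hat = sum / (n_c (K - 2))`` with
    ``K = N M (M - 1)`` ordered pairs per component.
    """
    comps = _components(residuals)
    N, M = comps[0].shape
    if M < 2:
        raise ValueError("exchangeable alpha estimation requires M >= 2")
    K = N * M * (M - 1)
    denom = len(comps) * (K - 2)
    if denom <= 0:
        logger.warning("too few pairs (K=%d); falling back to independence", K)
        return 0.0
    num = 0.0
    for e in comps:
        s = e.sum(axis=1)
        num += float(np.sum(s * s - np.sum(e * e, axis=1)))
    return float(np.clip(num / denom, 0.0, ALPHA_MAX))


def estimate_alpha(structure: str, residuals: ResidualSet) -> float:
    if structure == "independence":
        return 0.0
    if structure == "ar1":
        return estimate_alpha_ar1(residuals)
    if structure == "exchangeable":
        return estimate_alpha_exchangeable(residuals)
    raise ValueError(f"unknown structure {structure!r}")
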