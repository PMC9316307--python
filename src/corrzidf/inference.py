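"""Per-feature Wald tests and study-wide FDR control.

Differential abundance is assessed on the count-part coefficients
``beta_v`` (by default the treatment-group effect) using the robust
sandwich covariance; raw p-values are adjusted across features with the
Benjamini-Hochberg step-up procedure.  Features that could not be tested
(all-zero, or non-converged fits) are excluded from the BH family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gee import FitResult

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    feature_id: str
    status: str
    estimate: float = np.nan   # tested beta_v coefficient (first, if several)
    se: float = np.nan
    wald_stat: float = np.nan
    df: int = 0
    p_raw: float = np.nan
    p_adj: float = np.nan
    alpha_hat: float = np.nan
    structure: str = ""
    n_iter: int = 0


def wald_test(fit: FitResult, which=None) -> tuple[float, int, float]:
    """Wald chi-square test of selected count-part coefficients.

    ``which`` indexes into ``beta_v``; the default is the first
    non-intercept coefficient (the group effect under the standard
    intercept + group design).  Returns ``(W, df, p)`` with
    ``W = b' Sigma_b^{-1} b`` and ``p`` the upper chi-square tail on
    ``df = len(which)`` degrees of freedom.  A singular covariance block
    yields ``(nan, df, nan)``.
    """
    if fit.theta_hat is None or fit.sigma_beta is None:
        raise ValueError("fit carries no estimates to test")
    if which is None:
        which = [1] if fit.theta_hat.p_v > 1 else [0]
    which = list(which)
    b = fit.theta_hat.beta_v[which]
    cov = fit.beta_v_cov()[np.ix_(which, which)]
    df = len(which)
    try:
        W = float(b @ np.linalg.solve(cov, b))
    except np.linalg.LinAlgError:
        logger.warning("singular covariance block in Wald test")
        return np.nan, df, np.nan
    if W < 0:
        W = 0.0
    return W, df, float(stats.chi2.sf(W, df))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family size ``m`` and stay NaN.
    """
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def test_features(fits: dict, which=None, structure: str = "") -> list[TestResult]:
    """Wald-test every fitted feature and BH-adjust across the testable ones."""
    results = []
    for fid, fit in fits.items():
        r = TestResult(feature_id=str(fid), status=fit.status,
                       structure=fit.structure, n_iter=fit.n_iter,
                       alpha_hat=fit.alpha_hat)
        if fit.theta_hat is not None and fit.sigma_beta is not None:
            w = which
            if w is None:
                w = [1] if fit.theta_hat.p_v > 1 else [0]
            W, df, p = wald_test(fit, w)
            r.wald_stat, r.df = W, df
            r.estimate = float(fit.theta_hat.beta_v[w[0]])
            r.se = float(np.sqrt(max(fit.beta_v_cov()[w[0], w[0]], 0.0)))
            if fit.status == "ok":
                r.p_raw = p
        results.append(r)
    p = np.array([r.p_raw for r in results])
    padj = bh_adjust(p)
    for r, q in zip(results, padj):
        r.p_adj = float(q) if np.isfinite(q) else np.nan
    n_skip = sum(r.status != "ok" for r in results)
    if n_skip:
        logger.info("%d features excluded from the BH family (status != ok)", n_skip)
    return results


def results_table(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"feature_id": r.feature_id, "status": r.status, "estimate": r.estimate,
          "se": r.se, "alpha_hat": r.alpha_hat, "wald": r.wald_stat, "df": r.df,
          "p_raw": r.p_raw, "p_adj": r.p_adj, "structure": r.structure,
          "n_iter": r.n_iter} for r in results]
    )


def summarize_run(results: list[TestResult], alpha_fdr: float = 0.05,
                  truth=None) -> dict:
    """Study-level summary: feature counts and, given truth labels from a
    simulation, empirical FPR and TPR after BH adjustment.

    ``truth`` maps feature_id -> bool (True = differentially abundant).
    """
    table = results_table(results)
    sig = table["p_adj"] < alpha_fdr
    out = {
        "n_features": len(table),
        "n_tested": int(table["p_raw"].notna().sum()),
        "n_significant": int(sig.sum()),
        "fdr_threshold": alpha_fdr,
        "table": table,
    }
    if truth is not None:
        is_daf = table["feature_id"].map(lambda f: bool(truth[f])).to_numpy()
        tested = table["p_raw"].notna().to_numpy()
        sig = sig.to_numpy()
        n_null = int((tested & ~is_daf).sum())
        n_alt = int((tested & is_daf).sum())
        out["fpr"] = float((sig & ~is_daf).sum() / n_null) if n_null else np.nan
        out["tpr"] = float((sig & is_daf).sum() / n_alt) if n_alt else np.nan
    return out
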