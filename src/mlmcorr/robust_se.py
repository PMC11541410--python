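"""Cluster-robust covariance estimators (CR0/CR1/CR2) and Satterthwaite df.

CR0 is the plain sandwich on the (possibly GLS-weighted) fit; CR1 applies a
degrees-of-freedom scaling; CR2 is the bias-reduced linearisation, which
rescales each cluster's residual by an adjustment matrix ``A_j`` chosen so
the variance estimator is exactly unbiased when the working covariance
model is correct.  The accompanying Satterthwaite degrees of freedom match
the first two moments of the variance estimator viewed as a quadratic form
in the errors under the working model; they depend on the design and
working covariance only, never on the outcome.

The working covariance is the fitted model-based ``V_j`` for RI/RS fits and
the independence (identity) model for OLS fits, matching the estimation
weights in both cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mlmcorr.lmm_core import DesignError, FittedModel

__all__ = [
    "CorrectedInference",
    "cr0_cov",
    "cr1_cov",
    "cr2_cov",
    "satterthwaite_df",
    "robust_inference",
    "coef_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectedInference:
    """Single-coefficient t test under one covariance correction."""

    term: str
    estimate: float
    se: float
    df: float
    t: float
    p: float
    correction: str


def _default_working(fit: FittedModel) -> str:
    return "independence" if fit.spec.kind == "ols" else "model_based"


def _working_blocks(fit: FittedModel, working: str | None) -> list[np.ndarray]:
    working = working or _default_working(fit)
    if working == "model_based":
        return fit.V_blocks()
    if working == "independence":
        return [fit.sigma2 * np.eye(len(y)) for y in fit.y_blocks]
    raise ValueError(f"unknown working model {working!r}")


def cr0_cov(fit: FittedModel, working: str | None = None) -> np.ndarray:
    """Plain cluster sandwich on the fitted weights."""
    M = fit.cov_gls
    W = _working_blocks(fit, working)
    resid = fit.residual_blocks()
    p = fit.p
    meat = np.zeros((p, p))
    for Xj, rj, Wj in zip(fit.X_blocks, resid, W):
        g = Xj.T @ np.linalg.solve(Wj, rj)
        meat += np.outer(g, g)
    return M @ meat @ M


def cr1_cov(fit: FittedModel, working: str | None = None,
            factor: str = "standard") -> np.ndarray:
    """CR0 scaled for the cluster count.

    ``factor="standard"`` applies J/(J-1) to the variance matrix;
    ``factor="sqrt"`` applies sqrt(J/(J-1)) instead (an alternative scaling
    sometimes quoted for the variance matrix).
    """
    J = fit.J
    if J < 2:
        raise DesignError("CR1 requires at least 2 clusters")
    c = J / (J - 1.0)
    if factor == "sqrt":
        c = np.sqrt(c)
    elif factor != "standard":
        raise ValueError(f"unknown CR1 factor {factor!r}")
    return c * cr0_cov(fit, working)


def _sym_sqrt(mat: np.ndarray, inverse: bool, clip: float = 1e-12):
    """Symmetric (pseudo-)square root via eigendecomposition.

    Eigenvalues below ``clip`` (relative to the largest) are treated as
    zero and pseudo-inverted; returns the matrix and a degeneracy flag.
    """
    w, U = np.linalg.eigh((mat + mat.T) / 2.0)
    wmax = max(float(w.max()), 0.0)
    thresh = clip * max(wmax, 1.0)
    degenerate = bool(np.any(w < thresh))
    w = np.clip(w, 0.0, None)
    if inverse:
        root = np.where(w > thresh, 1.0 / np.sqrt(np.where(w > thresh, w, 1.0)), 0.0)
    else:
        root = np.sqrt(w)
    return (U * root) @ U.T, degenerate


def _sym_sqrt_pair(mat: np.ndarray, clip: float = 1e-12):
    """Square root and inverse square root from a single eigendecomposition."""
    w, U = np.linalg.eigh((mat + mat.T) / 2.0)
    thresh = clip * max(float(w.max()), 1.0)
    w = np.clip(w, 0.0, None)
    root = np.sqrt(w)
    iroot = np.where(w > thresh, 1.0 / np.where(w > thresh, root, 1.0), 0.0)
    return (U * root) @ U.T, (U * iroot) @ U.T


def _cr2_pieces(fit: FittedModel, working: str | None = None):
    """Per-cluster CR2 ingredients, cached on the fit.

    Returns (Phi_blocks, A_blocks, B_blocks) where
    ``B_j = Phi_j^-1 X_j M`` maps a contrast to the cluster score and
    ``A_j`` is the symmetric adjustment satisfying
    ``A_j (Phi_j - X_j M X_j') A_j = Phi_j``.
    """
    key = working or _default_working(fit)
    cache = getattr(fit, "_cr2_cache", None)
    if cache is None:
        cache = {}
        fit._cr2_cache = cache
    if key in cache:
        return cache[key]
    M = fit.cov_gls
    Phi = _working_blocks(fit, working)
    A_blocks, B_blocks = [], []
    warned = False
    for Xj, Pj in zip(fit.X_blocks, Phi):
        half, ihalf = _sym_sqrt_pair(Pj)
        G = ihalf @ (Pj - Xj @ M @ Xj.T) @ ihalf
        Ginv_half, degenerate = _sym_sqrt(G, inverse=True)
        if degenerate and not warned:
            logger.warning("CR2 adjustment degenerate for at least one "
                           "cluster; using pseudo-inverse square root")
            warned = True
        A_blocks.append(half @ Ginv_half @ ihalf)
        B_blocks.append(np.linalg.solve(Pj, Xj) @ M)
    cache[key] = (Phi, A_blocks, B_blocks)
    return cache[key]


def cr2_cov(fit: FittedModel, working: str | None = None) -> np.ndarray:
    """Bias-reduced linearisation sandwich with adjusted residuals."""
    _, A_blocks, B_blocks = _cr2_pieces(fit, working)
    resid = fit.residual_blocks()
    p = fit.p
    meat_like = np.zeros((p, p))
    for Aj, Bj, rj in zip(A_blocks, B_blocks, resid):
        g = Bj.T @ (Aj @ rj)  # already includes M on the left
        meat_like += np.outer(g, g)
    return meat_like


def satterthwaite_df(fit: FittedModel, index: int,
                     working: str | None = None) -> float:
    """Estimated degrees of freedom for the CR2 t test of one coefficient.

    Moment-matching of the CR2 variance estimator as a quadratic form in
    the errors under the working covariance: ``df = tr(Omega)^2 /
    tr(Omega^2)`` with ``Omega_jk`` the working covariance of the
    per-cluster score contributions.  Requires the estimation weights to be
    the inverse working covariance, which holds for every fit produced by
    this package.  The result does not depend on the outcome values.
    """
    Phi, A_blocks, B_blocks = _cr2_pieces(fit, working)
    M = fit.cov_gls
    c = np.zeros(fit.p)
    c[index] = 1.0
    # g_j = A_j' Phi_j^-1 X_j M c ; scores s_j = g_j' r_j
    g_blocks = [Aj.T @ (Bj @ c) for Aj, Bj in zip(A_blocks, B_blocks)]
    qdiag = np.array([g @ Pj @ g for g, Pj in zip(g_blocks, Phi)])
    Wmat = np.stack([Xj.T @ g for Xj, g in zip(fit.X_blocks, g_blocks)])
    Omega = np.diag(qdiag) - Wmat @ M @ Wmat.T
    tr = float(np.trace(Omega))
    tr2 = float(np.sum(Omega * Omega))
    if tr2 <= 0 or tr <= 0:
        logger.warning("degenerate quadratic form in Satterthwaite df "
                       "(coefficient %d)", index)
        return float("nan")
    return tr * tr / tr2


_COV_FUNCS = {"CR0": cr0_cov, "CR1": cr1_cov, "CR2": cr2_cov}


def robust_inference(fit: FittedModel, correction: str = "CR2",
                     working: str | None = None,
                     terms: list[int] | None = None) -> list[CorrectedInference]:
    """Tidy per-coefficient t tests under a cluster-robust correction.

    CR2 uses the estimated Satterthwaite df; CR0/CR1 fall back to the
    conventional J - 1.
    """
    correction = correction.upper()
    if correction not in _COV_FUNCS:
        raise ValueError(f"unknown correction {correction!r}")
    cov = _COV_FUNCS[correction](fit, working)
    idx = range(fit.p) if terms is None else terms
    out = []
    for i in idx:
        se = float(np.sqrt(cov[i, i]))
        if correction == "CR2":
            df = satterthwaite_df(fit, i, working)
        else:
            df = float(fit.J - 1)
        est = float(fit.gamma[i])
        tstat = est / se if se > 0 else float("nan")
        p = (2.0 * stats.t.sf(abs(tstat), df)
             if np.isfinite(df) and df > 0 else float("nan"))
        out.append(CorrectedInference(
            term=fit.labels[i], estimate=est, se=se, df=df, t=tstat,
            p=float(p), correction=correction))
    return out


def coef_table(inferences: list[CorrectedInference]) -> pd.DataFrame:
    """Coefficient table with columns term, estimate, se, df, t, p, correction."""
    return pd.DataFrame([vars(ci) for ci in inferences])
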