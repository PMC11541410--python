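"""Kenward-Roger small-sample adjustment for REML fixed-effect inference.

Inflates the GLS covariance of the fixed effects for the uncertainty in
the estimated variance parameters (second-order Taylor expansion around
the REML estimates, with the expected information of the variance
parameters), and supplies moment-matched degrees of freedom for
single-coefficient t tests.  Because the marginal covariance is linear in
the natural variance parameters ``(sigma2, vech T)``, the second-derivative
terms of the expansion vanish.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mlmcorr.lmm_core import FittedModel
from mlmcorr.robust_se import CorrectedInference

__all__ = ["KRResult", "kr_adjusted_cov", "kr_df", "kr_inference"]

logger = logging.getLogger(__name__)


@dataclass
class KRResult:
    """Adjusted covariance and per-coefficient tests."""

    labels: tuple[str, ...]
    gamma: np.ndarray
    cov_adjusted: np.ndarray
    se: np.ndarray
    df: np.ndarray
    t: np.ndarray
    p: np.ndarray

    def to_inferences(self) -> list[CorrectedInference]:
        return [CorrectedInference(
            term=self.labels[i], estimate=float(self.gamma[i]),
            se=float(self.se[i]), df=float(self.df[i]), t=float(self.t[i]),
            p=float(self.p[i]), correction="KR") for i in range(len(self.gamma))]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(ci) for ci in self.to_inferences()])


def _dT_bases(q: int) -> list[np.ndarray]:
    """Derivatives of T with respect to vech(T) (natural scale)."""
    out = []
    for a in range(q):
        for b in range(a, q):
            S = np.zeros((q, q))
            S[a, b] = 1.0
            S[b, a] = 1.0
            out.append(S)
    return out


def _kr_core(fit: FittedModel):
    """P_a, Q_ab, expected information and Phi for the variance parameters.

    Parameters are ordered (sigma2, vech T).  Derivative blocks are
    ``dV_j/dsigma2 = I`` and ``dV_j/dtau_ab = Z_j (E_ab + E_ba) Z_j'``
    (diagonal basis matrices are not doubled).
    """
    if fit.Z_blocks is None:
        raise ValueError("Kenward-Roger requires an RI or RS fit")
    q = fit.q
    p = fit.p
    S_list = _dT_bases(q)
    n_par = 1 + len(S_list)

    Phi = fit.cov_gls
    P = [np.zeros((p, p)) for _ in range(n_par)]
    Q = [[np.zeros((p, p)) for _ in range(n_par)] for _ in range(n_par)]
    S1 = np.zeros((n_par, n_par))

    for Xj, Zj, Vj in zip(fit.X_blocks, fit.Z_blocks, fit.V_blocks()):
        n = Vj.shape[0]
        Vi = np.linalg.inv(Vj)
        ViX = Vi @ Xj
        ViZ = Vi @ Zj
        ZtViZ = Zj.T @ ViZ            # q x q
        ZtViX = Zj.T @ ViX            # q x p
        Vi2 = Vi @ Vi
        XtVi2X = Xj.T @ Vi2 @ Xj
        ZtVi2Z = Zj.T @ Vi2 @ Zj
        ZtVi2X = Zj.T @ Vi2 @ Xj
        XtVi3X = Xj.T @ Vi2 @ ViX

        # dV blocks: index 0 = sigma2 (identity), 1.. = Z S Z'
        # P_a = X' Vi dV_a Vi X
        P[0] += XtVi2X
        for k, S in enumerate(S_list, start=1):
            P[k] += ZtViX.T @ S @ ZtViX

        # Q_ab = X' Vi dV_a Vi dV_b Vi X ; S1_ab = tr(Vi dV_a Vi dV_b)
        S1[0, 0] += float(np.sum(Vi * Vi))
        Q[0][0] += XtVi3X
        for k, S in enumerate(S_list, start=1):
            # tr(Vi^2 Z S Z') = tr(S Z'Vi^2 Z)
            S1[0, k] += float(np.sum(S * ZtVi2Z))
            # Q_0k = X'Vi Vi ZSZ' Vi X = (X'Vi2 Z) S (Z'Vi X)
            q0k = ZtVi2X.T @ S @ ZtViX
            Q[0][k] += q0k
            Q[k][0] += q0k.T
            for m, Sm in enumerate(S_list, start=1):
                if m < k:
                    continue
                # tr(Vi ZSZ' Vi ZSmZ') = tr(S M Sm M) with M = Z'ViZ
                S1[k, m] += float(np.sum((S @ ZtViZ @ Sm) * ZtViZ))
                # X'Vi ZSZ' Vi ZSmZ' Vi X
                qkm = ZtViX.T @ S @ ZtViZ @ Sm @ ZtViX
                Q[k][m] += qkm
                if m != k:
                    Q[m][k] += qkm.T

    S1[1:, 0] = S1[0, 1:]
    for k in range(1, n_par):
        for m in range(k + 1, n_par):
            S1[m, k] = S1[k, m]

    info = np.zeros((n_par, n_par))
    for a in range(n_par):
        for b in range(n_par):
            info[a, b] = 0.5 * (S1[a, b]
                                - 2.0 * float(np.trace(Phi @ Q[a][b]))
                                + float(np.trace(Phi @ P[a] @ Phi @ P[b])))
    return Phi, P, Q, info


def kr_adjusted_cov(fit: FittedModel, return_aux: bool = False):
    """Kenward-Roger adjusted covariance of the fixed effects.

    ``Phi_A = Phi + 2 Phi [ sum_ab W_ab (Q_ab - P_a Phi P_b) ] Phi`` with
    ``W`` the inverse expected information of the variance parameters.
    Singular information (boundary fits) falls back to a pseudo-inverse
    with a logged warning.
    """
    Phi, P, Q, info = _kr_core(fit)
    n_par = info.shape[0]
    try:
        W = np.linalg.inv(info)
        if not np.all(np.isfinite(W)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.warning("singular variance-parameter information; "
                       "using pseudo-inverse (boundary fit?)")
        W = np.linalg.pinv(info)
    U = np.zeros_like(Phi)
    for a in range(n_par):
        for b in range(n_par):
            U += W[a, b] * (Q[a][b] - P[a] @ Phi @ P[b])
    cov_adj = Phi + 2.0 * Phi @ U @ Phi
    if return_aux:
        return cov_adj, {"Phi": Phi, "P": P, "W": W}
    return cov_adj


def _df_from_aux(aux: dict, index: int) -> float:
    Phi, P, W = aux["Phi"], aux["P"], aux["W"]
    v = Phi[index, index]
    grads = np.array([(Phi @ Pa @ Phi)[index, index] for Pa in P])
    var_v = float(grads @ W @ grads)
    if var_v <= 0 or v <= 0:
        logger.warning("non-positive moment estimate in KR df "
                       "(coefficient %d)", index)
        return float("nan")
    return 2.0 * v * v / var_v


def kr_df(fit: FittedModel, index: int) -> float:
    """Moment-matched degrees of freedom for one coefficient's t test."""
    _, aux = kr_adjusted_cov(fit, return_aux=True)
    return _df_from_aux(aux, index)


def kr_inference(fit: FittedModel) -> KRResult:
    """Adjusted SEs, df, t and p for every fixed effect of a REML fit."""
    cov_adj, aux = kr_adjusted_cov(fit, return_aux=True)
    p = fit.p
    se = np.sqrt(np.clip(np.diag(cov_adj), 0.0, None))
    df = np.array([_df_from_aux(aux, i) for i in range(p)])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.gamma / se
    pvals = np.full(p, np.nan)
    ok = np.isfinite(df) & (df > 0) & np.isfinite(t)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    return KRResult(labels=fit.labels, gamma=fit.gamma, cov_adjusted=cov_adj,
                    se=se, df=df, t=t, p=pvals)
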