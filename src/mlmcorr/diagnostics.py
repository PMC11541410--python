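"""Homoscedasticity diagnostics for fitted two-level models.

Breusch-Pagan-style Lagrange multiplier tests at each level: squared
level-1 residuals (or squared empirical-Bayes random-effect predictions at
level 2) are regressed on candidate predictors, and ``n * R^2`` of the
auxiliary regression is referred to a chi-square distribution with one
degree of freedom per predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mlmcorr.lmm_core import FittedModel
from mlmcorr.synthetic_data import ClusteredDataset

__all__ = ["BPTestResult", "eb_random_effects", "level1_residuals",
           "bp_test_level1", "bp_test_level2", "residual_profiles"]


@dataclass(frozen=True)
class BPTestResult:
    level: int
    statistic: float
    df: int
    p: float
    predictors: tuple[str, ...]


def eb_random_effects(fit: FittedModel) -> np.ndarray:
    """Empirical-Bayes (shrunken) predictions of the random effects, (J, q)."""
    if fit.Z_blocks is None:
        raise ValueError("OLS fits have no random effects")
    resid = fit.residual_blocks()
    out = np.empty((fit.J, fit.q))
    for j, (Zj, Vj, rj) in enumerate(zip(fit.Z_blocks, fit.V_blocks(), resid)):
        out[j] = fit.T @ Zj.T @ np.linalg.solve(Vj, rj)
    return out


def level1_residuals(fit: FittedModel) -> np.ndarray:
    """Within-cluster residuals ``y - X gamma - Z u_hat`` (stacked)."""
    resid = fit.residual_blocks()
    if fit.Z_blocks is None:
        return np.concatenate(resid)
    u = eb_random_effects(fit)
    return np.concatenate([rj - Zj @ u[j]
                           for j, (Zj, rj) in enumerate(zip(fit.Z_blocks, resid))])


def _lm_test(sq_resid: np.ndarray, design: np.ndarray) -> tuple[float, float]:
    """(LM statistic, R^2) of regressing squared residuals on the design."""
    n = len(sq_resid)
    X = np.column_stack([np.ones(n), design])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate auxiliary regression "
                         "(constant or collinear predictors)")
    beta, *_ = np.linalg.lstsq(X, sq_resid, rcond=None)
    fitted = X @ beta
    tss = float(np.sum((sq_resid - sq_resid.mean()) ** 2))
    if tss == 0:
        return 0.0, 0.0  # constant residuals: degenerate, stat 0
    rss = float(np.sum((sq_resid - fitted) ** 2))
    r2 = 1.0 - rss / tss
    return n * r2, r2


def bp_test_level1(fit: FittedModel, data: ClusteredDataset,
                   predictors: list[str]) -> BPTestResult:
    """LM test of level-1 residual variance against observation predictors.

    The auxiliary regression is linear in the named columns; to detect
    variance patterns that are symmetric around the predictor mean (e.g. a
    |x|-shaped spread), supply a suitable variance covariate such as an
    absolute-value column.
    """
    if not predictors:
        raise ValueError("at least one predictor is required")
    r1 = level1_residuals(fit)
    design = data.df[list(predictors)].to_numpy(dtype=float)
    stat, _ = _lm_test(r1 ** 2, design)
    df = len(predictors)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return BPTestResult(level=1, statistic=float(stat), df=df, p=p,
                        predictors=tuple(predictors))


def bp_test_level2(fit: FittedModel, data: ClusteredDataset,
                   cluster_predictors: list[str],
                   term: int = 0) -> BPTestResult:
    """LM test of random-effect variance against cluster-level predictors.

    ``term`` selects which random effect's squared empirical-Bayes
    predictions form the response (0 = intercept).
    """
    if not cluster_predictors:
        raise ValueError("at least one cluster predictor is required")
    if fit.J < 10:
        warnings.warn("level-2 BP test is poorly calibrated with J < 10",
                      UserWarning, stacklevel=2)
    u = eb_random_effects(fit)[:, term]
    cdf = (data.df.groupby("cluster_id", sort=False)[list(cluster_predictors)]
           .first())
    cdf = cdf.loc[fit.cluster_ids]
    stat, _ = _lm_test(u ** 2, cdf.to_numpy(dtype=float))
    df = len(cluster_predictors)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return BPTestResult(level=2, statistic=float(stat), df=df, p=p,
                        predictors=tuple(cluster_predictors))


def residual_profiles(fit: FittedModel, data: ClusteredDataset,
                      level1_predictor: str = "x",
                      cluster_predictor: str = "z") -> dict[str, pd.DataFrame]:
    """Plot-ready residual tables.

    Returns a ``level1`` table of (predictor, residual) pairs and, for
    mixed fits, one ``level2_<term>`` table of (cluster predictor,
    predicted random effect) per random term.
    """
    out = {"level1": pd.DataFrame({
        "predictor": data.df[level1_predictor].to_numpy(dtype=float),
        "residual": level1_residuals(fit),
    })}
    if fit.Z_blocks is not None:
        u = eb_random_effects(fit)
        zc = (data.df.groupby("cluster_id", sort=False)[cluster_predictor]
              .first().loc[fit.cluster_ids].to_numpy(dtype=float))
        for k, name in enumerate(fit.spec.random):
            label = "intercept" if name == "1" else name
            out[f"level2_{label}"] = pd.DataFrame({
                "predictor": zc, "random_effect": u[:, k]})
    return out
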