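"""OLS and REML-GLS fitting of two-level linear models.

Random-intercept (RI) and random-slope (RS) models are fit by restricted
maximum likelihood with the residual variance profiled out.  The
random-effects covariance ``T`` is parameterised through the Cholesky
factor of ``G = T / sigma^2`` so positive semidefiniteness (including
boundary fits with zero variances) is enforced by construction.

The fitted object keeps the per-cluster design blocks ``X_j``, ``Z_j`` and
outcomes, which downstream covariance corrections need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from mlmcorr.synthetic_data import ClusteredDataset

__all__ = [
    "ModelSpec",
    "FittedModel",
    "DesignError",
    "EstimationError",
    "build_design",
    "fit_ols",
    "fit_lmm",
    "gls_fixed_effects",
]

logger = logging.getLogger(__name__)

_RANDOM_TERMS = {"ols": (), "ri": ("1",), "rs": ("1", "x")}


class DesignError(ValueError):
    """Invalid design for the requested model or correction."""


class EstimationError(RuntimeError):
    """Estimation failed (rank deficiency, singular system)."""


@dataclass(frozen=True)
class ModelSpec:
    """Analysis-model specification.

    ``fixed`` lists term strings: ``"1"`` (intercept), a column name, or a
    product ``"a:b"``.  The random part follows the model kind: none for
    OLS, intercept for RI, intercept plus the slope terms in ``random`` for
    RS (default the x-slope).
    """

    kind: str = "rs"
    fixed: tuple[str, ...] = ("1", "z", "x", "x:z")
    random: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ols", "ri", "rs"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.random is None:
            object.__setattr__(self, "random", _RANDOM_TERMS[self.kind])

    @classmethod
    def from_formula(cls, formula: str, random: str = "intercept+x") -> "ModelSpec":
        """Build a spec from e.g. ``"y ~ x + z + x:z"`` and a random part.

        ``random`` is one of ``"none"``, ``"intercept"`` or
        ``"intercept+<slope>"``.
        """
        lhs, rhs = (s.strip() for s in formula.split("~"))
        if lhs != "y":
            raise ValueError("outcome column must be named 'y'")
        fixed = ("1",) + tuple(t.strip() for t in rhs.split("+") if t.strip())
        random = random.strip().lower()
        if random == "none":
            return cls(kind="ols", fixed=fixed)
        if random == "intercept":
            return cls(kind="ri", fixed=fixed)
        if random.startswith("intercept+"):
            slopes = tuple(s.strip() for s in random[len("intercept+"):].split("+"))
            return cls(kind="rs", fixed=fixed, random=("1",) + slopes)
        raise ValueError(f"unrecognised random part {random!r}")


def _term_column(df, term: str) -> np.ndarray:
    if term == "1":
        return np.ones(len(df))
    if ":" in term:
        a, b = term.split(":")
        return (df[a.strip()] * df[b.strip()]).to_numpy(dtype=float)
    return df[term].to_numpy(dtype=float)


def build_design(data: ClusteredDataset, spec: ModelSpec):
    """Stacked design matrices and per-cluster index slices."""
    df = data.df
    X = np.column_stack([_term_column(df, t) for t in spec.fixed])
    Z = (np.column_stack([_term_column(df, t) for t in spec.random])
         if spec.random else None)
    y = df["y"].to_numpy(dtype=float)
    ids = df["cluster_id"].to_numpy()
    uniq, starts = np.unique(ids, return_index=True)
    order = np.argsort(starts)
    uniq = uniq[order]
    # contiguity check: simulated data is block-sorted; user CSVs may not be
    pos = {c: i for i, c in enumerate(uniq)}
    codes = np.fromiter((pos[c] for c in ids), dtype=int, count=len(ids))
    if np.any(np.diff(codes) < 0):
        sort = np.argsort(codes, kind="stable")
        X, y, codes = X[sort], y[sort], codes[sort]
        if Z is not None:
            Z = Z[sort]
    counts = np.bincount(codes, minlength=len(uniq))
    edges = np.concatenate([[0], np.cumsum(counts)])
    slices = [slice(edges[j], edges[j + 1]) for j in range(len(uniq))]
    return X, Z, y, uniq, slices


@dataclass
class FittedModel:
    """A fitted OLS/RI/RS model with per-cluster blocks."""

    spec: ModelSpec
    labels: tuple[str, ...]
    gamma: np.ndarray
    cov_gls: np.ndarray
    sigma2: float
    T: np.ndarray | None
    reml: float | None
    converged: bool
    boundary: bool
    cluster_ids: np.ndarray
    X_blocks: list[np.ndarray]
    Z_blocks: list[np.ndarray] | None
    y_blocks: list[np.ndarray]
    _V_blocks: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def J(self) -> int:
        return len(self.X_blocks)

    @property
    def N(self) -> int:
        return sum(len(y) for y in self.y_blocks)

    @property
    def p(self) -> int:
        return self.X_blocks[0].shape[1]

    @property
    def q(self) -> int:
        return 0 if self.Z_blocks is None else self.Z_blocks[0].shape[1]

    def V_blocks(self) -> list[np.ndarray]:
        """Per-cluster marginal covariance ``Z_j T Z_j' + sigma2 I``."""
        if self._V_blocks is None:
            out = []
            for j in range(self.J):
                n = len(self.y_blocks[j])
                V = self.sigma2 * np.eye(n)
                if self.Z_blocks is not None:
                    Zj = self.Z_blocks[j]
                    V = V + Zj @ self.T @ Zj.T
                out.append(V)
            self._V_blocks = out
        return self._V_blocks

    def residual_blocks(self) -> list[np.ndarray]:
        """Marginal residuals ``y_j - X_j gamma`` per cluster."""
        return [self.y_blocks[j] - self.X_blocks[j] @ self.gamma
                for j in range(self.J)]

    def se_gls(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_gls))

    def theta(self) -> np.ndarray:
        """Natural-scale variance parameters ``(sigma2, vech T)``."""
        if self.T is None:
            return np.array([self.sigma2])
        q = self.T.shape[0]
        vech = [self.T[a, b] for a in range(q) for b in range(a, q)]
        return np.array([self.sigma2] + vech)


def _check_rank(X: np.ndarray, labels: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via QR with pivoting
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [labels[i] for i in piv[len(diag):]]
        raise EstimationError(f"design matrix is rank deficient; collinear "
                              f"columns include {bad}")


def fit_ols(data: ClusteredDataset, spec: ModelSpec | None = None) -> FittedModel:
    """Ordinary least squares with identity-scaled cluster blocks."""
    if spec is None:
        spec = ModelSpec(kind="ols")
    if spec.kind != "ols":
        raise ValueError("fit_ols requires an OLS model spec")
    X, _, y, uniq, slices = build_design(data, spec)
    _check_rank(X, spec.fixed)
    N, p = X.shape
    gamma, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ gamma
    dof = max(N - p, 1)
    sigma2 = float(resid @ resid / dof)
    XtX_inv = np.linalg.inv(X.T @ X)
    return FittedModel(
        spec=spec, labels=spec.fixed, gamma=gamma,
        cov_gls=sigma2 * XtX_inv, sigma2=sigma2, T=None, reml=None,
        converged=True, boundary=False, cluster_ids=uniq,
        X_blocks=[X[s] for s in slices], Z_blocks=None,
        y_blocks=[y[s] for s in slices],
    )


class _RemlProblem:
    """Profiled REML criterion from per-cluster sufficient statistics.

    All cluster loops are batched: for ``q`` random effects only
    ``q x q`` systems are factorised per criterion evaluation, so the cost
    per evaluation is O(J q^3) independent of cluster sizes.
    """

    def __init__(self, X, Z, y, slices):
        self.N, self.p = X.shape
        self.q = Z.shape[1]
        self.J = len(slices)
        self.ZtZ = np.stack([Z[s].T @ Z[s] for s in slices])
        self.ZtX = np.stack([Z[s].T @ X[s] for s in slices])
        self.Zty = np.stack([Z[s].T @ y[s] for s in slices])
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-cluster right-hand sides [Zty | ZtX], (J, q, p+1)
        self.R = np.concatenate([self.Zty[:, :, None], self.ZtX], axis=2)
        self._tril = np.tril_indices(self.q)
        self._eye = np.eye(self.q)

    def _L(self, params: np.ndarray) -> np.ndarray:
        L = np.zeros((self.q, self.q))
        L[self._tril] = params
        return L

    def pieces(self, params: np.ndarray):
        """(A, b, s, logdetM) for V0 = I + Z G Z', G = LL'."""
        L = self._L(params)
        M = self._eye + L.T @ self.ZtZ @ L
        LtR = L.T @ self.R
        if self.q == 1:
            det = M[:, 0, 0]
            logdetM = float(np.sum(np.log(det)))
            S = LtR / det[:, None, None]
        elif self.q == 2:
            det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
            if np.any(det <= 0) or np.any(M[:, 0, 0] <= 0):
                return None
            logdetM = float(np.sum(np.log(det)))
            Minv = np.empty_like(M)
            Minv[:, 0, 0] = M[:, 1, 1]
            Minv[:, 1, 1] = M[:, 0, 0]
            Minv[:, 0, 1] = -M[:, 0, 1]
            Minv[:, 1, 0] = -M[:, 1, 0]
            Minv /= det[:, None, None]
            S = Minv @ LtR
        else:
            try:
                C = np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                return None
            logdetM = 2.0 * float(
                np.sum(np.log(np.diagonal(C, axis1=1, axis2=2))))
            S = np.linalg.solve(M, LtR)
        # corrections Sum_j (L'Zt*)' M^-1 (L'Zt*)
        corr = np.einsum("jab,jac->bc", LtR, S)
        s = self.yty - corr[0, 0]
        b = self.Xty - corr[0, 1:]
        A = self.XtX - corr[1:, 1:]
        return A, b, s, logdetM

    def neg2_reml(self, params: np.ndarray) -> float:
        out = self.pieces(params)
        if out is None:
            return np.inf
        A, b, s, logdetM = out
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        try:
            g0 = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf
        ypy = s - b @ g0
        if not np.isfinite(ypy) or ypy <= 0:
            return np.inf
        dof = self.N - self.p
        sigma2 = ypy / dof
        return dof * np.log(sigma2) + logdetM + logdetA + dof

    def solution(self, params: np.ndarray):
        A, b, s, _ = self.pieces(params)
        g0 = np.linalg.solve(A, b)
        sigma2 = float((s - b @ g0) / (self.N - self.p))
        cov = sigma2 * np.linalg.inv(A)
        L = self._L(params)
        T = sigma2 * (L @ L.T)
        return g0, cov, sigma2, T


def _start_values(X, Z, y, slices, q: int) -> np.ndarray:
    """Moment-based starting values for the scaled Cholesky factor."""
    gamma, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ gamma
    sigma2 = max(float(resid @ resid / max(len(y) - X.shape[1], 1)), 1e-8)
    means = np.array([resid[s].mean() for s in slices])
    nbar = np.mean([s.stop - s.start for s in slices])
    tau = max(float(np.var(means, ddof=1) - sigma2 / nbar), 0.05 * sigma2)
    g = np.sqrt(tau / sigma2)
    start = np.zeros(q * (q + 1) // 2)
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = g
    start[:] = L[np.tril_indices(q)]
    return start


def fit_lmm(data: ClusteredDataset, spec: ModelSpec,
            max_restarts: int = 3, tol: float = 1e-8,
            boundary_tol: float = 1e-6) -> FittedModel:
    """REML fit of an RI or RS model with GLS fixed effects.

    Optimizer failures after restarts yield a flagged (``converged=False``)
    fit rather than an exception; boundary fits (a random-effect variance
    estimated at zero) are retained and flagged.
    """
    if spec.kind not in ("ri", "rs"):
        raise ValueError("fit_lmm requires an RI or RS model spec")
    X, Z, y, uniq, slices = build_design(data, spec)
    if len(slices) < 2:
        raise DesignError("at least 2 clusters are required")
    _check_rank(X, spec.fixed)
    prob = _RemlProblem(X, Z, y, slices)
    q = prob.q

    rng = np.random.default_rng(12345)
    start = _start_values(X, Z, y, slices, q)
    best = None
    for attempt in range(max_restarts + 1):
        x0 = start if attempt == 0 else start * np.exp(
            rng.normal(scale=0.5, size=start.shape)) + rng.normal(
            scale=0.05, size=start.shape)
        res = optimize.minimize(
            prob.neg2_reml, x0, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": tol, "maxiter": 4000,
                     "maxfev": 4000})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best.success and np.isfinite(best.fun):
            break

    converged = bool(best.success and np.isfinite(best.fun))
    if not np.isfinite(best.fun):
        logger.warning("REML optimisation failed to find a finite criterion")
        params = start
    else:
        params = best.x
    gamma, cov, sigma2, T = prob.solution(params)
    boundary = bool(np.any(np.diag(T) <= boundary_tol * sigma2))
    return FittedModel(
        spec=spec, labels=spec.fixed, gamma=gamma, cov_gls=cov,
        sigma2=sigma2, T=T, reml=float(best.fun), converged=converged,
        boundary=boundary, cluster_ids=uniq,
        X_blocks=[X[s] for s in slices],
        Z_blocks=[Z[s] for s in slices],
        y_blocks=[y[s] for s in slices],
    )


def gls_fixed_effects(X_blocks: Sequence[np.ndarray],
                      y_blocks: Sequence[np.ndarray],
                      V_blocks: Sequence[np.ndarray]):
    """GLS estimator and covariance from per-cluster blocks.

    Returns ``(gamma_hat, cov)`` with
    ``cov = (sum_j X_j' V_j^-1 X_j)^-1`` and
    ``gamma_hat = cov @ sum_j X_j' V_j^-1 y_j``.
    """
    p = X_blocks[0].shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for Xj, yj, Vj in zip(X_blocks, y_blocks, V_blocks):
        Vi = np.linalg.solve(Vj, np.column_stack([Xj, yj]))
        A += Xj.T @ Vi[:, :p]
        b += Xj.T @ Vi[:, p]
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular GLS information matrix") from exc
    return cov @ b, cov
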