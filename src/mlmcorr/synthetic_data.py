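"""Generation of two-level clustered data with controlled heteroscedasticity.

The generator draws from

    y_ij = g00 + g01*z_j + g10*x_ij + g11*z_j*x_ij
           + m2_j * u0_j + m2_j * u1_j * x_ij + m1_ij * e_ij

where ``z_j`` is a cluster-level predictor, ``x_ij`` an observation-level
predictor (both standard normal, x has no between-cluster variance), the
random effects ``u0, u1`` and residual ``e`` are independent normals, and
``m2_j`` / ``m1_ij`` are heteroscedasticity multipliers.  Under the
homoscedastic pattern (VP1) both multipliers are identically one; under
VP2/VP3 they are ``k * sqrt(n_j) * lambda(v)`` with ``lambda(v) = |v| + 1``
(variance largest away from the predictor mean) or ``1 / (|v| + 1)``
(variance smallest away from the mean).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariancePattern",
    "ConditionSpec",
    "VarianceSpec",
    "ClusteredDataset",
    "make_condition_grid",
    "cluster_sizes",
    "tau0_sq_from_icc",
    "lambda_vp",
    "k_factor",
    "generate_dataset",
    "grid_to_config",
    "grid_from_config",
]


class VariancePattern(str, Enum):
    """Variance pattern at one level of the model."""

    VP1 = "VP1"  # homoscedastic
    VP2 = "VP2"  # conditional variance largest away from the predictor mean
    VP3 = "VP3"  # conditional variance smallest away from the predictor mean


def _as_pattern(pattern: "VariancePattern | str") -> VariancePattern:
    return VariancePattern(pattern)


# Calibration constants equalising the average marginal variance of the
# heteroscedastic conditions with the homoscedastic baseline, indexed by
# (average cluster size, pattern).  They track the analytic calibration
# k = 1 / sqrt(n_bar * E[lambda(v)^2]) for v ~ N(0, 1), which gives
# approximately 0.24, 0.71, 0.10 and 0.29 for the four cells below; the
# multiplier k * sqrt(n_bar) * lambda(v) then has mean-square ~1 so the
# average variance is preserved while the 5:1 cluster-size gradient and the
# lambda shape remain.  (Note k must decrease in n_bar and is larger for
# the shrinking pattern VP3 than for VP2.)
K_TABLE: dict[tuple[int, VariancePattern], float] = {
    (5, VariancePattern.VP2): 0.25,
    (5, VariancePattern.VP3): 0.73,
    (30, VariancePattern.VP2): 0.10,
    (30, VariancePattern.VP3): 0.30,
}


def calibrated_k(n_bar: int, pattern: VariancePattern | str,
                 n_grid: int = 200_001) -> float:
    """Numerically calibrated alternative to the tabulated constants.

    Solves ``E[(k sqrt(n_bar) lambda(v))^2] = 1`` for ``v ~ N(0,1)`` by
    quadrature, so the average heteroscedastic variance matches the
    homoscedastic baseline exactly.
    """
    pattern = _as_pattern(pattern)
    if pattern is VariancePattern.VP1:
        return 1.0
    v = np.linspace(-8.0, 8.0, n_grid)
    w = np.exp(-0.5 * v * v) / np.sqrt(2.0 * np.pi)
    lam2 = np.asarray(lambda_vp(v, pattern)) ** 2
    mean_sq = np.trapezoid(lam2 * w, v)
    return float(1.0 / np.sqrt(n_bar * mean_sq))


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the simulation design grid."""

    J: int
    n_bar: int
    icc: float
    gamma01: float
    gamma10: float
    balanced: bool
    vp_l1: VariancePattern
    vp_l2: VariancePattern
    gamma00: float = 1.0
    gamma11: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.icc < 1.0):
            raise ValueError(f"icc must be in [0, 1), got {self.icc}")
        if self.J < 2:
            raise ValueError("J must be at least 2")
        if self.n_bar < 1:
            raise ValueError("n_bar must be positive")
        object.__setattr__(self, "vp_l1", _as_pattern(self.vp_l1))
        object.__setattr__(self, "vp_l2", _as_pattern(self.vp_l2))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vp_l1"] = self.vp_l1.value
        d["vp_l2"] = self.vp_l2.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionSpec":
        return cls(**d)

    def with_gammas(self, gamma01: float | None = None,
                    gamma10: float | None = None) -> "ConditionSpec":
        kw = {}
        if gamma01 is not None:
            kw["gamma01"] = gamma01
        if gamma10 is not None:
            kw["gamma10"] = gamma10
        return replace(self, **kw)


@dataclass(frozen=True)
class VarianceSpec:
    """Variance components and heteroscedasticity calibration factors."""

    tau0_sq: float
    tau1_sq: float
    sigma2: float = 1.0
    tau01: float = 0.0
    k_l1: float = 1.0
    k_l2: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0 or self.tau0_sq < 0 or self.tau1_sq < 0:
            raise ValueError("variances must be nonnegative")

    @classmethod
    def from_condition(cls, cond: ConditionSpec, sigma2: float = 1.0) -> "VarianceSpec":
        """Variance spec implied by a design condition.

        The random-intercept and random-slope variances are set equal, derived
        from the conditional ICC; the calibration factor for each level is
        looked up from the (n_bar, pattern) table.
        """
        tau = tau0_sq_from_icc(cond.icc, sigma2)
        return cls(
            tau0_sq=tau,
            tau1_sq=tau,
            sigma2=sigma2,
            tau01=0.0,
            k_l1=k_factor(cond.n_bar, cond.vp_l1),
            k_l2=k_factor(cond.n_bar, cond.vp_l2),
        )


def make_condition_grid(
    J: Sequence[int] = (15, 30, 50),
    n_bar: Sequence[int] = (5, 30),
    icc: Sequence[float] = (0.1, 0.3),
    gamma10: Sequence[float] = (0.0, 0.3),
    gamma01: Sequence[float] = (0.0, 0.3),
    balanced: Sequence[bool] = (True, False),
    vp_l1: Sequence[VariancePattern | str] = tuple(VariancePattern),
    vp_l2: Sequence[VariancePattern | str] = tuple(VariancePattern),
) -> list[ConditionSpec]:
    """Full-factorial grid over the eight varied design factors.

    With the defaults this enumerates 3*2*2*2*2*2*3*3 = 864 unique cells.
    """
    grid = [
        ConditionSpec(J=j, n_bar=n, icc=rho, gamma01=g01, gamma10=g10,
                      balanced=b, vp_l1=_as_pattern(v1), vp_l2=_as_pattern(v2))
        for j, n, rho, g10, g01, b, v1, v2 in itertools.product(
            J, n_bar, icc, gamma10, gamma01, balanced, vp_l1, vp_l2)
    ]
    return grid


def cluster_sizes(J: int, n_bar: int, balanced: bool) -> np.ndarray:
    """Per-cluster sizes for a balanced or five-strata unbalanced design.

    Unbalanced designs split the ``J`` clusters into five equal strata with
    target sizes ``n_bar/3, 2*n_bar/3, n_bar, 4*n_bar/3, 5*n_bar/3``,
    integer-rounded by largest remainder so the total stays ``J * n_bar`` and
    the largest stratum is roughly five times the smallest.
    """
    if balanced:
        return np.full(J, n_bar, dtype=int)
    if J % 5 != 0:
        raise ValueError(f"unbalanced design requires J divisible by 5, got J={J}")
    raw = n_bar * np.array([1 / 3, 2 / 3, 1.0, 4 / 3, 5 / 3])
    strata = np.floor(raw).astype(int)
    shortfall = int(round(raw.sum())) - int(strata.sum())
    if shortfall:
        order = np.argsort(-(raw - np.floor(raw)), kind="stable")
        for i in order[:shortfall]:
            strata[i] += 1
    if strata.min() < 1:
        raise ValueError(f"n_bar={n_bar} too small for the five-strata design")
    assert strata.sum() == 5 * n_bar
    return np.repeat(strata, J // 5)


def tau0_sq_from_icc(icc: float, sigma2: float = 1.0) -> float:
    """Random-intercept variance implied by a conditional ICC.

    Solves ``icc = tau0^2 / (tau0^2 + sigma^2)`` for ``tau0^2``.
    """
    if not (0.0 <= icc < 1.0):
        raise ValueError(f"icc must be in [0, 1), got {icc}")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return sigma2 * icc / (1.0 - icc)


def lambda_vp(v, pattern: VariancePattern | str):
    """Heteroscedasticity shape multiplier evaluated at predictor value(s)."""
    pattern = _as_pattern(pattern)
    v = np.asarray(v, dtype=float)
    if pattern is VariancePattern.VP1:
        out = np.ones_like(v)
    elif pattern is VariancePattern.VP2:
        out = np.abs(v) + 1.0
    else:
        out = 1.0 / (np.abs(v) + 1.0)
    return out if out.ndim else float(out)


def k_factor(n_bar: int, pattern: VariancePattern | str) -> float:
    """Calibration constant for the (average cluster size, pattern) pair."""
    pattern = _as_pattern(pattern)
    if pattern is VariancePattern.VP1:
        return 1.0
    try:
        return K_TABLE[(int(n_bar), pattern)]
    except KeyError:
        raise ValueError(
            f"no calibration constant tabulated for n_bar={n_bar}, "
            f"pattern={pattern.value}"
        ) from None


class ClusteredDataset:
    """Long-format clustered data with one row per observation.

    Wraps a :class:`pandas.DataFrame` with columns ``cluster_id``, ``y`` and
    predictor columns (``x`` at the observation level, ``z`` constant within
    cluster for simulated data).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True) -> None:
        required = {"cluster_id", "y"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)
        if validate and "z" in df.columns:
            nun = self.df.groupby("cluster_id")["z"].nunique()
            if (nun > 1).any():
                bad = nun[nun > 1].index.tolist()
                raise ValueError(f"z varies within cluster(s) {bad}")

    @property
    def cluster_ids(self) -> np.ndarray:
        """Unique cluster labels in order of first appearance."""
        return self.df["cluster_id"].unique()

    @property
    def sizes(self) -> np.ndarray:
        counts = self.df["cluster_id"].value_counts()
        return counts.loc[self.cluster_ids].to_numpy()

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClusteredDataset":
        return cls(pd.read_csv(path))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ClusteredDataset(n_obs={self.n_obs}, "
                f"n_clusters={self.n_clusters})")


def _level2_multiplier(cond: ConditionSpec, vs: VarianceSpec,
                       z: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    if cond.vp_l2 is VariancePattern.VP1:
        return np.ones_like(z)
    return vs.k_l2 * np.sqrt(sizes) * lambda_vp(z, cond.vp_l2)


def _level1_multiplier(cond: ConditionSpec, vs: VarianceSpec,
                       x: np.ndarray, n_per_obs: np.ndarray) -> np.ndarray:
    if cond.vp_l1 is VariancePattern.VP1:
        return np.ones_like(x)
    return vs.k_l1 * np.sqrt(n_per_obs) * lambda_vp(x, cond.vp_l1)


def generate_dataset(cond: ConditionSpec, vs: VarianceSpec | None = None,
                     seed=0) -> ClusteredDataset:
    """Draw one dataset under the given design condition.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`.  Identical (cond, vs, seed) triples
    yield bitwise-identical datasets.
    """
    if vs is None:
        vs = VarianceSpec.from_condition(cond)
    rng = np.random.default_rng(seed)
    sizes = cluster_sizes(cond.J, cond.n_bar, cond.balanced)
    J, N = cond.J, int(sizes.sum())

    z = rng.standard_normal(J)
    u0 = rng.standard_normal(J) * np.sqrt(vs.tau0_sq)
    u1 = rng.standard_normal(J) * np.sqrt(vs.tau1_sq)
    x = rng.standard_normal(N)
    e = rng.standard_normal(N) * np.sqrt(vs.sigma2)

    m2 = _level2_multiplier(cond, vs, z, sizes)
    n_per_obs = np.repeat(sizes, sizes)
    m1 = _level1_multiplier(cond, vs, x, n_per_obs)

    z_obs = np.repeat(z, sizes)
    u0_obs = np.repeat(m2 * u0, sizes)
    u1_obs = np.repeat(m2 * u1, sizes)

    y = (cond.gamma00 + cond.gamma01 * z_obs + cond.gamma10 * x
         + cond.gamma11 * z_obs * x + u0_obs + u1_obs * x + m1 * e)

    df = pd.DataFrame({
        "cluster_id": np.repeat(np.arange(J), sizes),
        "y": y,
        "x": x,
        "z": z_obs,
    })
    return ClusteredDataset(df, validate=False)


def grid_to_config(grid: Iterable[ConditionSpec], path) -> None:
    """Serialise a condition grid to YAML or JSON (by file extension)."""
    payload = {"conditions": [c.to_dict() for c in grid]}
    path = Path(path)
    text = (json.dumps(payload, indent=1) if path.suffix == ".json"
            else yaml.safe_dump(payload, sort_keys=False))
    path.write_text(text)


def grid_from_config(path) -> list[ConditionSpec]:
    path = Path(path)
    raw = (json.loads(path.read_text()) if path.suffix == ".json"
           else yaml.safe_load(path.read_text()))
    return [ConditionSpec.from_dict(d) for d in raw["conditions"]]
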