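"""Monte Carlo evaluation metrics for standard-error estimators.

Relative bias of estimated standard errors against the empirical sampling
standard deviation, empirical rejection rates with the liberal-criterion
classification (robust in [0.025, 0.075] at nominal .05), and power
corrected by the null 5% p-value quantile when the type I error rate is
inflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConditionSummary",
    "relative_bias",
    "rejection_rate",
    "bradley_class",
    "corrected_power",
    "BRADLEY_LOWER",
    "BRADLEY_UPPER",
]

BRADLEY_LOWER = 0.025
BRADLEY_UPPER = 0.075


@dataclass
class ConditionSummary:
    """Per-condition, per-method, per-coefficient evaluation metrics."""

    condition_id: str
    method: str
    coefficient: str
    R_effective: int
    rel_bias: float | None = None
    rejection_rate: float | None = None
    corrected_power: float | None = None
    bradley: str | None = None


def relative_bias(se_estimates: Sequence[float], empirical_sd: float) -> float:
    """Mean of (estimated SE - empirical SD) / empirical SD over replications."""
    se = np.asarray(se_estimates, dtype=float)
    if se.size < 2:
        raise ValueError("relative bias requires at least 2 replications")
    if not (empirical_sd > 0):
        raise ValueError("empirical_sd must be positive")
    return float(np.mean((se - empirical_sd) / empirical_sd))


def rejection_rate(p_values: Sequence[float], alpha: float = 0.05) -> float:
    """Proportion of replications with p below alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return float(np.mean(p < alpha))


def bradley_class(rate: float) -> str:
    """Classify a type I error rate against the liberal criterion bounds."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be a proportion")
    if rate > BRADLEY_UPPER:
        return "liberal"
    if rate < BRADLEY_LOWER:
        return "conservative"
    return "robust"


def corrected_power(null_p: Sequence[float], alt_p: Sequence[float],
                    alpha: float = 0.05) -> float:
    """Power with the cutoff deflated to the null 5% p-value quantile.

    When the empirical type I error exceeds ``alpha``, the cutoff becomes
    the smaller of ``alpha`` and the empirical ``alpha`` quantile
    (inverse-CDF definition) of the null p values; a deflated null keeps
    the nominal cutoff.  By construction the result never exceeds the raw
    power at ``alpha``.
    """
    null_p = np.asarray(null_p, dtype=float)
    alt_p = np.asarray(alt_p, dtype=float)
    if null_p.size == 0 or alt_p.size == 0:
        raise ValueError("null and alternative p-value lists must be non-empty")
    cutoff = alpha
    if rejection_rate(null_p, alpha) > alpha:
        q = float(np.quantile(null_p, alpha, method="inverted_cdf"))
        cutoff = min(alpha, q)
    return float(np.mean(alt_p < cutoff))
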