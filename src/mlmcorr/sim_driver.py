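"""Monte Carlo driver: conditions x replications x method combinations.

Each replication generates one dataset, fits the requested analysis models
(OLS, random intercept, random slope), applies the requested covariance
correction (CR2 with Satterthwaite df, or Kenward-Roger on the RS fit) and
records per-coefficient inference.  Seeding is hierarchical — replication
``r`` of condition ``c`` uses the stream ``SeedSequence([root, c, r])`` —
so runs are reproducible, resumable and safely parallelisable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mlmcorr.evaluation import bradley_class, corrected_power, rejection_rate, relative_bias
from mlmcorr.kr_correction import kr_inference
from mlmcorr.lmm_core import ModelSpec, fit_lmm, fit_ols
from mlmcorr.robust_se import robust_inference
from mlmcorr.synthetic_data import ConditionSpec, VarianceSpec, generate_dataset

__all__ = ["RunConfig", "METHODS", "run_replication", "run_condition",
           "run_grid", "aggregate", "attach_corrected_power", "format_table"]

logger = logging.getLogger(__name__)

# method name -> (model kind, correction)
METHODS: dict[str, tuple[str, str]] = {
    "RS-KR": ("rs", "KR"),
    "RS-CRSEs": ("rs", "CR2"),
    "RI-CRSEs": ("ri", "CR2"),
    "OLS-CRSEs": ("ols", "CR2"),
}

_COND_FIELDS = ("J", "n_bar", "icc", "gamma01", "gamma10", "balanced",
                "vp_l1", "vp_l2")


@dataclass
class RunConfig:
    """Settings for a Monte Carlo run."""

    conditions: Sequence[ConditionSpec]
    R: int = 500
    root_seed: int = 0
    methods: tuple[str, ...] = tuple(METHODS)
    alpha: float = 0.05
    out_dir: str | Path | None = None
    n_jobs: int = 1
    terms: tuple[str, ...] = ("z", "x")

    def __post_init__(self) -> None:
        if self.R < 2:
            raise ValueError("R must be at least 2")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _cond_id(cond: ConditionSpec) -> str:
    return (f"J{cond.J}_n{cond.n_bar}_icc{cond.icc}_g01-{cond.gamma01}"
            f"_g10-{cond.gamma10}_{'bal' if cond.balanced else 'unbal'}"
            f"_{cond.vp_l1.value}_{cond.vp_l2.value}")


def _cond_record(cond: ConditionSpec) -> dict:
    d = cond.to_dict()
    return {k: d[k] for k in _COND_FIELDS}


def run_replication(cond: ConditionSpec, methods: Sequence[str], seed,
                    terms: Sequence[str] = ("z", "x"),
                    vs: VarianceSpec | None = None) -> list[dict]:
    """Fit every requested method on one generated dataset."""
    data = generate_dataset(cond, vs=vs, seed=seed)
    kinds = {METHODS[m][0] for m in methods}
    fits: dict[str, object] = {}
    if "ols" in kinds:
        fits["ols"] = fit_ols(data)
    for kind in ("ri", "rs"):
        if kind in kinds:
            fits[kind] = fit_lmm(data, ModelSpec(kind=kind))

    records = []
    base = _cond_record(cond)
    for m in methods:
        kind, correction = METHODS[m]
        fit = fits[kind]
        idx = [fit.labels.index(t) for t in terms]
        try:
            if correction == "KR":
                res = kr_inference(fit)
                infs = [res.to_inferences()[i] for i in idx]
            else:
                infs = robust_inference(fit, correction=correction, terms=idx)
        except Exception as exc:  # hard failure -> flagged records
            logger.warning("inference failed for %s: %s", m, exc)
            infs = None
        for k, t in enumerate(terms):
            rec = dict(base)
            rec.update(method=m, term=t, converged=fit.converged,
                       boundary=getattr(fit, "boundary", False))
            if infs is None:
                rec.update(estimate=np.nan, se=np.nan, df=np.nan,
                           t_stat=np.nan, p=np.nan, flagged=True)
            else:
                ci = infs[k]
                ok = (np.isfinite(ci.se) and ci.se > 0
                      and np.isfinite(ci.df) and ci.df > 0
                      and np.isfinite(ci.p) and fit.converged)
                rec.update(estimate=ci.estimate, se=ci.se, df=ci.df,
                           t_stat=ci.t, p=ci.p, flagged=not ok)
            records.append(rec)
    return records


def _run_one(cond, methods, terms, root_seed, cond_index, rep):
    seed = np.random.SeedSequence([root_seed, cond_index, rep])
    recs = run_replication(cond, methods, seed, terms)
    for r in recs:
        r["rep"] = rep
    return recs


def run_condition(cond: ConditionSpec, config: RunConfig,
                  cond_index: int = 0) -> pd.DataFrame:
    """All replications for one condition, as a tidy record frame."""
    if config.n_jobs != 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=config.n_jobs)(
            delayed(_run_one)(cond, config.methods, config.terms,
                              config.root_seed, cond_index, r)
            for r in range(config.R))
    else:
        chunks = [_run_one(cond, config.methods, config.terms,
                           config.root_seed, cond_index, r)
                  for r in range(config.R)]
    records = [rec for chunk in chunks for rec in chunk]
    df = pd.DataFrame(records)
    df.insert(0, "condition_id", _cond_id(cond))
    return df


def run_grid(config: RunConfig) -> pd.DataFrame:
    """Run every condition; optionally write one records CSV per condition."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for i, cond in enumerate(config.conditions):
        df = run_condition(cond, config, cond_index=i)
        if out_dir:
            df.to_csv(out_dir / f"records_{i:04d}.csv", index=False)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _is_null(frame: pd.DataFrame) -> pd.Series:
    g = np.where(frame["term"] == "z", frame["gamma01"], frame["gamma10"])
    return pd.Series(g == 0, index=frame.index)


def aggregate(records: pd.DataFrame,
              by: Sequence[str] = ("condition_id",),
              alpha: float = 0.05) -> pd.DataFrame:
    """Per-cell evaluation metrics from replication records.

    Flagged replications are dropped from every metric; ``R_effective``
    reports how many remain.  ``rejection_rate`` is reported for every
    cell; it is a type I error rate where the tested coefficient is zero
    (``is_null``) and raw power otherwise.  Relative bias uses the
    within-cell empirical SD of the estimates as the target.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    rows = []
    keys = list(by) + ["method", "term"]
    for key, cell in records.groupby(keys, sort=False):
        valid = cell[~cell["flagged"].astype(bool)]
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row["R_requested"] = len(cell)
        row["R_effective"] = len(valid)
        row["is_null"] = bool(_is_null(cell).all())
        if len(valid) >= 2 and valid["estimate"].std(ddof=1) > 0:
            sd = float(valid["estimate"].std(ddof=1))
            row["empirical_sd"] = sd
            row["mean_se"] = float(valid["se"].mean())
            row["rel_bias"] = relative_bias(valid["se"].to_numpy(), sd)
        else:
            row["empirical_sd"] = np.nan
            row["mean_se"] = np.nan
            row["rel_bias"] = np.nan
        if len(valid):
            rate = rejection_rate(valid["p"].to_numpy(), alpha)
            row["rejection_rate"] = rate
            row["bradley"] = bradley_class(rate) if row["is_null"] else None
        else:
            row["rejection_rate"] = np.nan
            row["bradley"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def attach_corrected_power(records: pd.DataFrame,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Corrected power for alternative cells matched to their null cell.

    A cell's null partner is the condition identical in every design
    factor except that the tested coefficient is zero.  Returns one row
    per (alternative cell, method, term).
    """
    rows = []
    match_cols = ["J", "n_bar", "icc", "balanced", "vp_l1", "vp_l2",
                  "method", "term"]
    rec = records[~records["flagged"].astype(bool)].copy()
    rec["gcol"] = np.where(rec["term"] == "z", rec["gamma01"], rec["gamma10"])
    rec["other"] = np.where(rec["term"] == "z", rec["gamma10"], rec["gamma01"])
    for key, grp in rec.groupby(match_cols + ["other"], sort=False):
        nulls = grp[grp["gcol"] == 0]
        alts = grp[grp["gcol"] != 0]
        if nulls.empty or alts.empty:
            continue
        for gval, alt in alts.groupby("gcol"):
            row = dict(zip(match_cols + ["other"], key))
            row["gamma_alt"] = float(gval)
            row["power_raw"] = rejection_rate(alt["p"].to_numpy(), alpha)
            row["power_corrected"] = corrected_power(
                nulls["p"].to_numpy(), alt["p"].to_numpy(), alpha)
            row["type1"] = rejection_rate(nulls["p"].to_numpy(), alpha)
            rows.append(row)
    if not rows:
        raise ValueError("no matched null/alternative condition pairs found")
    return pd.DataFrame(rows)


def format_table(summary: pd.DataFrame, style: str = "table3",
                 value: str | None = None) -> pd.DataFrame:
    """Pivot a summary frame into the layout of the report tables.

    ``table1``/``table2`` show relative bias with balance as columns;
    ``table3``/``table4`` show rejection rates with the level-2 variance
    pattern as columns.
    """
    if style in ("table1", "table2"):
        value = value or "rel_bias"
        index = [c for c in ("icc", "J", "method") if c in summary.columns]
        cols = [c for c in ("vp_l2", "balanced") if c in summary.columns]
    elif style in ("table3", "table4"):
        value = value or "rejection_rate"
        index = [c for c in ("icc", "J", "method") if c in summary.columns]
        cols = [c for c in ("vp_l2",) if c in summary.columns]
    else:
        raise ValueError(f"unknown table style {style!r}")
    return summary.pivot_table(index=index, columns=cols, values=value,
                               aggfunc="mean")
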