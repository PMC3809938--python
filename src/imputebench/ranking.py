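"""Rank aggregation of Monte-Carlo errors into a method x metric summary.

Per deletion fraction: simulation errors are averaged per (method, metric,
site, pool); methods are ranked 1 (lowest error, best) .. n within each
(metric, site, pool) with midranks for ties; ranks are averaged across sites
within each pool, then across the pools, giving one number per method per
metric; the Average column is the row-wise mean over the four metrics.
Smaller values indicate more accurate imputation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AggregationError, InputError

__all__ = ["METRICS", "average_over_sims", "rank_methods", "aggregate_ranks", "best_worst"]

logger = logging.getLogger(__name__)

METRICS = ["rmse", "lrmse", "rae", "rae_l2"]
METRIC_LABELS = {"rmse": "RMSE", "lrmse": "LRMSE", "rae": "RAE", "rae_l2": "RAEL2"}


def average_over_sims(reports: pd.DataFrame) -> pd.DataFrame:
    """Mean error per (method, metric, site, pool) over simulations.

    Rows flagged ``failed`` are excluded (count logged); a group with no
    valid rows raises.
    """
    df = reports
    if "failed" in df.columns:
        n_failed = int(df["failed"].sum())
        if n_failed:
            logger.info("excluding %d failed simulation report(s) from averages", n_failed)
        df = df[~df["failed"]]
    if df.empty:
        raise AggregationError("no valid simulation reports to average")
    mean = df.groupby(["method", "site", "pool"], sort=True)[METRICS].mean().reset_index()
    # every (method, site, pool) cell must have had at least one valid sim
    expected = (reports.groupby(["method", "site", "pool"]).size().index
                .difference(mean.set_index(["method", "site", "pool"]).index))
    if len(expected):
        raise AggregationError(f"cells with no valid simulations: {list(expected)}")
    return mean


def rank_methods(errors: pd.Series) -> pd.Series:
    """Ascending ranks (1 = lowest error); ties get midranks."""
    if len(errors) < 2:
        raise InputError("ranking needs at least 2 methods")
    if errors.isna().any():
        raise InputError(f"missing error value for method(s): {list(errors.index[errors.isna()])}")
    return pd.Series(rankdata(errors.to_numpy()), index=errors.index)


def aggregate_ranks(mean_errors: pd.DataFrame) -> pd.DataFrame:
    """Two-level rank aggregation: sites within pool, then pools.

    ``mean_errors`` is the output of :func:`average_over_sims`.  Returns the
    method x (RMSE, LRMSE, RAE, RAEL2, Average) table, methods sorted by
    label.  Requires complete factorial coverage.
    """
    methods = sorted(mean_errors["method"].unique())
    sites = sorted(mean_errors["site"].unique())
    pools = sorted(mean_errors["pool"].unique())
    idx = mean_errors.set_index(["method", "site", "pool"]).index
    missing = [(m, s, p) for m in methods for s in sites for p in pools if (m, s, p) not in idx]
    if missing:
        raise AggregationError(f"incomplete factorial coverage; missing cells: {missing[:10]}")

    out = pd.DataFrame(index=pd.Index(methods, name="method"))
    for metric in METRICS:
        wide = mean_errors.pivot_table(index="method", columns=["site", "pool"],
                                       values=metric, sort=True)
        ranks = wide.apply(lambda col: rankdata(col.to_numpy()), axis=0,
                           result_type="broadcast")
        # sites-then-pools: mean over sites within each pool, then over pools
        per_pool = ranks.T.groupby(level="pool").mean().T
        out[METRIC_LABELS[metric]] = per_pool.mean(axis=1).reindex(methods)
    out["Average"] = out[[METRIC_LABELS[m] for m in METRICS]].mean(axis=1)
    return out


def best_worst(rank_table: pd.DataFrame) -> dict[str, dict[str, list[str]]]:
    """Argmin/argmax methods per column (ties reported as sets)."""
    if rank_table.isna().any().any():
        raise InputError("rank table contains missing values")
    result: dict[str, dict[str, list[str]]] = {}
    for col in rank_table.columns:
        v = rank_table[col]
        result[col] = {
            "best": sorted(v.index[v == v.min()]),
            "worst": sorted(v.index[v == v.max()]),
        }
    return result
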