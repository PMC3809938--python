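"""Detection calls (Present / Marginal / Absent) and the completeness filter.

Each probe pair yields a discrimination score ``(PM - MM) / (PM + MM)``.
Under the null the probe set's median score equals a small threshold tau;
the alternative is that it exceeds tau.  A one-sided exact Wilcoxon
signed-rank test of the scores against tau gives a p-value per probe set per
array, converted to a call with two significance cut-offs:

* Present  : p < alpha1
* Marginal : alpha1 <= p < alpha2
* Absent   : p >= alpha2

Defaults tau = 0.015, alpha1 = 0.04, alpha2 = 0.06 are the classic MAS 5.0
presets.  With 11-20 probe pairs the exact null distribution is used (no
normal approximation): zero differences are dropped, tied magnitudes get
midranks, and the null distribution of the positive-rank sum is built by
convolution over the independent signs — equivalent to enumerating all 2^n
sign assignments.

The completeness filter retains, per site x pool cell, exactly the probe
sets called Present in every replicate; these rows form the complete
expression matrix handed to summarisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, InputError
from .synthetic import ProbeLevelTable

__all__ = [
    "DetectionParams",
    "discrimination_scores",
    "wilcoxon_one_sided_p",
    "detect",
    "percent_present",
    "filter_complete",
]

logger = logging.getLogger(__name__)

PRESENT, MARGINAL, ABSENT = "P", "M", "A"


@dataclass(frozen=True)
class DetectionParams:
    tau: float = 0.015
    alpha1: float = 0.04
    alpha2: float = 0.06

    def validate(self) -> None:
        if self.tau < 0:
            raise ConfigError("tau must be nonnegative")
        if not 0 < self.alpha1 < self.alpha2 < 1:
            raise ConfigError("significance levels must satisfy 0 < alpha1 < alpha2 < 1")

    def call(self, p_value: float) -> str:
        if p_value < self.alpha1:
            return PRESENT
        if p_value < self.alpha2:
            return MARGINAL
        return ABSENT


def discrimination_scores(pm, mm) -> np.ndarray:
    """Per probe pair ``(PM - MM) / (PM + MM)``; each score lies in (-1, 1)."""
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape or pm.ndim != 1 or pm.size < 1:
        raise InputError("pm and mm must be 1-d vectors of equal nonzero length")
    if np.any(pm <= 0) or np.any(mm <= 0):
        raise InputError("intensities must be strictly positive")
    return (pm - mm) / (pm + mm)


def _signed_rank_tail_p(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) under the exact signed-rank null with midranks.

    Signs are i.i.d. fair coin flips, so the null distribution of the
    positive-rank sum is the convolution of n two-point distributions
    {0, r_i}; a dynamic programme over doubled ranks (integers, since
    midranks are multiples of 1/2) reproduces the full 2^n enumeration.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for r in doubled:
        counts[r:top + r + 1] += counts[0:top + 1]
        top += int(r)
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_obs))
    return float(counts[w2:].sum())


def wilcoxon_one_sided_p(scores, tau: float) -> float:
    """Exact one-sided signed-rank p-value for H1: median(scores) > tau.

    Differences equal to tau are dropped before ranking (standard
    signed-rank practice); if every difference is zero the test is
    uninformative and 1.0 is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 1:
        raise InputError("scores must be a nonempty 1-d vector")
    d = scores - tau
    d = d[d != 0.0]
    if d.size == 0:
        logger.warning("all discrimination scores equal tau; returning p = 1.0")
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    return _signed_rank_tail_p(ranks, w_obs)


def detect(table: ProbeLevelTable, params: DetectionParams | None = None) -> pd.DataFrame:
    """One p-value and call per (probe set, sample).

    Returns a DataFrame with columns ``probe_set_id, sample_id, p_value,
    call``, ordered by probe set then sample.
    """
    params = params or DetectionParams()
    params.validate()
    probes = table.probes

    records: list[tuple[str, str, float, str]] = []
    for ps_id, group in probes.groupby("probe_set_id", sort=True):
        # pivot to (n_pairs x n_samples) keeping sample order
        piv_pm = group.pivot_table(index="probe_pair_index", columns="sample_id",
                                   values="pm", sort=True)
        piv_mm = group.pivot_table(index="probe_pair_index", columns="sample_id",
                                   values="mm", sort=True)
        for sample_id in piv_pm.columns:
            pm = piv_pm[sample_id].to_numpy()
            mm = piv_mm[sample_id].to_numpy()
            try:
                sc = discrimination_scores(pm, mm)
                p = wilcoxon_one_sided_p(sc, params.tau)
            except InputError as exc:
                raise InputError(f"probe set {ps_id}, sample {sample_id}: {exc}") from exc
            records.append((ps_id, sample_id, p, params.call(p)))
    return pd.DataFrame(records, columns=["probe_set_id", "sample_id", "p_value", "call"])


def percent_present(calls: pd.DataFrame, samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent-present per array and its mean per site x pool cell.

    Per array: ``100 * (#Present) / (#probe sets)``.  Per cell: the
    arithmetic mean over that cell's replicates.
    """
    n_sets = calls.groupby("sample_id")["probe_set_id"].nunique()
    expected = calls["probe_set_id"].nunique()
    if (n_sets != expected).any():
        missing = n_sets[n_sets != expected].index.tolist()
        raise InputError(f"samples missing calls for some probe sets: {missing}")
    known = set(n_sets.index)
    absent = [s for s in samples["sample_id"] if s not in known]
    if absent:
        raise InputError(f"samples missing calls entirely: {absent}")

    present = calls[calls["call"] == PRESENT].groupby("sample_id").size()
    per_array = (100.0 * present.reindex(n_sets.index, fill_value=0) / n_sets).rename("percent_present")
    per_array = per_array.reset_index().merge(samples, on="sample_id")

    per_cell = (per_array.groupby(["site", "pool"], sort=True)["percent_present"]
                .mean().rename("mean_percent_present").reset_index())
    return per_array[["sample_id", "site", "pool", "replicate", "percent_present"]], per_cell


def filter_complete(calls: pd.DataFrame, samples: pd.DataFrame, site: str, pool: str) -> list[str]:
    """Probe sets called Present in ALL replicates of one site x pool cell.

    Probe sets Absent or Marginal in one or more replicates are removed; the
    returned (sorted) ids define the rows of the cell's complete expression
    matrix.
    """
    cell = samples[(samples["site"] == site) & (samples["pool"] == pool)]
    if cell.empty:
        raise InputError(f"unknown site/pool cell: {site}/{pool}")
    cell_samples = list(cell["sample_id"])
    sub = calls[calls["sample_id"].isin(cell_samples)]
    got = sub["sample_id"].nunique()
    if got != len(cell_samples):
        raise InputError(f"calls missing for some replicates of {site}/{pool}")
    ok = (sub.assign(is_present=sub["call"] == PRESENT)
          .groupby("probe_set_id")["is_present"].all())
    return sorted(ok.index[ok])
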