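"""Probe-set summarisation in the MAS 5.0 style.

Three stages (the spatial zone-background step of the original chip
algorithm is deliberately omitted — it needs physical chip geometry, and the
synthetic data carries its background in a noise-floor term instead):

1. an *ideal mismatch* IM per probe pair, guaranteed to sit strictly below
   PM so that PM - IM is always a positive signal estimate;
2. a robust one-step Tukey-biweight average of ``log2(PM - IM)`` per probe
   set per array, giving ``signal = 2^biweight``;
3. scale normalisation: every array (column) is scaled so its trimmed mean
   hits a common target intensity (or, optionally, the first array's
   trimmed mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .errors import ConfigError, InputError, NumericError
from .synthetic import ProbeLevelTable

__all__ = [
    "PreprocessParams",
    "tukey_biweight",
    "ideal_mismatch",
    "summarize",
    "scale_normalize",
]


@dataclass(frozen=True)
class PreprocessParams:
    contrast_tau: float = 0.03
    scale_tau: float = 10.0
    target_intensity: float = 500.0
    trim_fraction: float = 0.02
    delta_floor: float = 2.0 ** -20
    biweight_c: float = 5.0
    biweight_epsilon: float = 1e-4
    #: normalise to the first column's trimmed mean instead of target_intensity
    baseline_array_mode: bool = False

    def validate(self) -> None:
        for name in ("contrast_tau", "scale_tau", "target_intensity",
                     "delta_floor", "biweight_c", "biweight_epsilon"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.trim_fraction < 0.5:
            raise ConfigError("trim_fraction must lie in [0, 0.5)")


def tukey_biweight(values, c: float = 5.0, epsilon: float = 1e-4) -> float:
    """One-step Tukey biweight location estimate.

    Centre = median, spread = ``c * MAD + epsilon``; points further than one
    spread from the centre get zero weight, the rest the quartic biweight
    ``(1 - u^2)^2``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise InputError("tukey_biweight needs a nonempty 1-d vector")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    u = (v - med) / (c * mad + epsilon)
    w = np.where(np.abs(u) <= 1.0, (1.0 - u**2) ** 2, 0.0)
    return float(np.sum(w * v) / np.sum(w))


def ideal_mismatch(pm, mm, params: PreprocessParams | None = None) -> np.ndarray:
    """Ideal mismatch per probe pair of one probe set on one array.

    Where MM < PM the mismatch is used as-is.  Otherwise the probe set's
    typical log-ratio SB = biweight(log2(PM/MM)) substitutes: IM = PM / 2^SB
    when SB exceeds ``contrast_tau``, else PM is shrunk by a smoothly tapered
    exponent so that 0 < IM < PM always holds.
    """
    params = params or PreprocessParams()
    params.validate()
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape or pm.ndim != 1:
        raise InputError("pm and mm must be 1-d vectors of equal length")
    if np.any(pm <= 0) or np.any(mm <= 0):
        raise InputError("intensities must be strictly positive")

    sb = tukey_biweight(np.log2(pm / mm), params.biweight_c, params.biweight_epsilon)
    if sb > params.contrast_tau:
        fallback = pm / 2.0 ** sb
    else:
        tapered = params.contrast_tau / (1.0 + (params.contrast_tau - sb) / params.scale_tau)
        fallback = pm / 2.0 ** tapered
    im = np.where(mm < pm, mm, fallback)
    return im


def summarize(table: ProbeLevelTable, retained, params: PreprocessParams | None = None,
              sample_ids=None) -> pd.DataFrame:
    """Expression matrix (retained probe sets x arrays) from probe-level data.

    Per probe set per array: ``signal = 2^biweight(log2(max(PM - IM,
    delta_floor)))``.  ``sample_ids`` restricts/orders the columns (default:
    sample-sheet order).
    """
    params = params or PreprocessParams()
    params.validate()
    retained = list(retained)
    probes = table.probes
    have = set(probes["probe_set_id"])
    missing = [r for r in retained if r not in have]
    if missing:
        raise InputError(f"retained probe sets absent from table: {missing[:5]}")
    if sample_ids is None:
        sample_ids = table.sample_ids

    sub = probes[probes["probe_set_id"].isin(retained) & probes["sample_id"].isin(sample_ids)]
    out = np.empty((len(retained), len(sample_ids)))
    col_of = {s: j for j, s in enumerate(sample_ids)}
    row_of = {r: i for i, r in enumerate(retained)}
    for (ps_id, sample_id), grp in sub.groupby(["probe_set_id", "sample_id"], sort=False):
        g = grp.sort_values("probe_pair_index")
        pm = g["pm"].to_numpy()
        mm = g["mm"].to_numpy()
        im = ideal_mismatch(pm, mm, params)
        log_signal = np.log2(np.maximum(pm - im, params.delta_floor))
        val = 2.0 ** tukey_biweight(log_signal, params.biweight_c, params.biweight_epsilon)
        out[row_of[ps_id], col_of[sample_id]] = val
    return pd.DataFrame(out, index=retained, columns=list(sample_ids))


def scale_normalize(matrix: pd.DataFrame, params: PreprocessParams | None = None) -> pd.DataFrame:
    """Scale every column so its trimmed mean equals the common target.

    In ``baseline_array_mode`` the target is the first column's trimmed
    mean.  Idempotent to floating-point tolerance.
    """
    params = params or PreprocessParams()
    params.validate()
    values = matrix.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise InputError("scale_normalize expects a complete, strictly positive matrix")
    tm = np.array([trim_mean(values[:, j], params.trim_fraction) for j in range(values.shape[1])])
    if np.any(tm <= 0):
        bad = matrix.columns[np.nonzero(tm <= 0)[0]].tolist()
        raise NumericError(f"column(s) with nonpositive trimmed mean: {bad}")
    target = tm[0] if params.baseline_array_mode else params.target_intensity
    scaled = values * (target / tm)[None, :]
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)
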