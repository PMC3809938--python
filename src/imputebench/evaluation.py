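"""Monte-Carlo evaluation of imputation accuracy by random deletion.

A complete positive expression matrix CD is degraded by masking a fixed
fraction of its cells uniformly at random without replacement; each
imputation method fills the holes, and the imputed matrix ID is scored on
the masked cells only with four error measures:

* RMSE     = sqrt( mean (yhat - y)^2 )
* RAE      = mean |yhat - y| / phi(y),  phi(y) = max(|y|, epsilon)
* LRMSE    = sqrt( mean (log yhat - log y)^2 )
* RAE-L2   = mean (yhat - y)^2 / y

Within one simulation every method faces the identical mask, so the
comparison is paired.  Per-simulation seeds are ``seed XOR sim_index`` so any
single simulation can be rerun in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, NumericError
from .imputation import MaskedMatrix, MethodConfig, impute

__all__ = [
    "EvalConfig",
    "delete_entries",
    "rmse",
    "rae",
    "lrmse",
    "rae_l2",
    "score",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


@dataclass(frozen=True)
class EvalConfig:
    deletion_fraction: float = 0.05
    n_simulations: int = 1000
    epsilon: float = 0.20
    log_base: str = "e"
    #: apply an outer square root to RAE-L2 (off by default)
    rae_l2_root: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.deletion_fraction < 1:
            raise ConfigError("deletion_fraction must lie in (0, 1)")
        if self.n_simulations < 1:
            raise ConfigError("n_simulations must be a positive integer")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.log_base not in _LOG_BASES:
            raise ConfigError("log_base must be one of 'e', '2', '10'")


def delete_entries(cd: pd.DataFrame, fraction: float, seed: int) -> MaskedMatrix:
    """Mask ``round(fraction * G * S)`` distinct cells uniformly at random.

    True values are stashed for scoring; the draw is deterministic per seed.
    Rounding is round-half-even.
    """
    values = cd.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise InputError("delete_entries expects a complete, strictly positive matrix")
    g, s = values.shape
    n_cells = g * s
    n_mask = round(fraction * n_cells)
    if n_mask == 0:
        raise InputError(f"fraction {fraction} would mask 0 of {n_cells} cells")
    if n_mask >= n_cells:
        raise InputError("fraction would mask every cell; nothing left observed")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_mask, replace=False)
    mask = np.zeros(n_cells, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(g, s)
    return MaskedMatrix(values=np.where(mask, np.nan, values), mask=mask, truth=values,
                        row_ids=[str(i) for i in cd.index],
                        col_ids=[str(c) for c in cd.columns])


def _check_pair(truth, est) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth, dtype=float)
    e = np.asarray(est, dtype=float)
    if t.shape != e.shape or t.ndim != 1 or t.size == 0:
        raise InputError("truth and estimate must be 1-d vectors of equal nonzero length")
    return t, e


def rmse(truth, est) -> float:
    """Root mean squared error over the masked cells."""
    t, e = _check_pair(truth, est)
    return float(np.sqrt(np.mean((e - t) ** 2)))


def rae(truth, est, epsilon: float = 0.20) -> float:
    """Relative absolute error; true values below epsilon are clamped so
    tiny denominators cannot dominate."""
    if epsilon <= 0:
        raise ConfigError("epsilon must be positive")
    t, e = _check_pair(truth, est)
    phi = np.maximum(np.abs(t), epsilon)
    return float(np.mean(np.abs(e - t) / phi))


def lrmse(truth, est, log_base: str = "e") -> float:
    """RMSE on the log scale (configurable base; rank order is base-invariant)."""
    if log_base not in _LOG_BASES:
        raise ConfigError("log_base must be one of 'e', '2', '10'")
    t, e = _check_pair(truth, est)
    if np.any(t <= 0):
        raise NumericError(f"nonpositive true value at cell {int(np.nonzero(t <= 0)[0][0])}")
    if np.any(e <= 0):
        raise NumericError(f"nonpositive estimate at cell {int(np.nonzero(e <= 0)[0][0])}")
    denom = math.log(_LOG_BASES[log_base])
    d = (np.log(e) - np.log(t)) / denom
    return float(np.sqrt(np.mean(d**2)))


def rae_l2(truth, est, root: bool = False) -> float:
    """Mean squared error relative to the true value, ``mean (yhat-y)^2 / y``.

    ``root=True`` applies an outer square root (alternative rendering)."""
    t, e = _check_pair(truth, est)
    if np.any(t <= 0):
        raise NumericError(f"nonpositive true value at cell {int(np.nonzero(t <= 0)[0][0])}")
    v = float(np.mean((e - t) ** 2 / t))
    return math.sqrt(v) if root else v


def score(m: MaskedMatrix, imputed_values: np.ndarray, cfg: EvalConfig) -> dict[str, float]:
    """All four error measures of one imputation on one masked matrix."""
    if m.truth is None:
        raise InputError("masked matrix carries no stashed truth; cannot score")
    t = m.truth[m.mask]
    e = np.asarray(imputed_values, dtype=float)[m.mask]
    neg = e < cfg.epsilon
    if neg.any():
        # log-domain measures need positive estimates; nonpositive or
        # near-zero predictions are clamped to the same epsilon floor the
        # relative-error measure uses
        logger.info("%d imputed value(s) below epsilon floored for log-scale scoring",
                    int(neg.sum()))
        e_pos = np.where(neg, cfg.epsilon, e)
    else:
        e_pos = e
    return {
        "rmse": rmse(t, e),
        "lrmse": lrmse(t, e_pos, cfg.log_base),
        "rae": rae(t, e, cfg.epsilon),
        "rae_l2": rae_l2(t, e, cfg.rae_l2_root),
        "n_missing": int(m.mask.sum()),
    }


def run_benchmark(cd: pd.DataFrame, methods: list[MethodConfig], cfg: EvalConfig,
                  site: str = "site1", pool: str = "A") -> pd.DataFrame:
    """Repeated deletion -> imputation -> scoring for one site x pool cell.

    Every method sees the identical mask within a simulation.  Failed method
    runs are flagged (``failed = True``) and carry NaN errors; downstream
    averaging excludes them.  Returns a long-format DataFrame with columns
    ``site pool sim method rmse lrmse rae rae_l2 n_missing failed``.
    """
    cfg.validate()
    labels = [mc.name for mc in methods]
    if len(set(labels)) != len(labels):
        raise ConfigError("method labels must be unique")
    records = []
    for sim in range(cfg.n_simulations):
        mask_seed = (cfg.seed ^ sim) % (2**31)
        masked = delete_entries(cd, cfg.deletion_fraction, mask_seed)
        for mc in methods:
            mc_run = mc if mc.seed == mask_seed else MethodConfig(
                **{**mc.__dict__, "seed": mask_seed})
            try:
                result = impute(masked, mc_run)
                errs = score(masked, result.values, cfg)
                failed = False
            except Exception:
                logger.exception("method %s failed on simulation %d", mc.name, sim)
                errs = {"rmse": np.nan, "lrmse": np.nan, "rae": np.nan,
                        "rae_l2": np.nan, "n_missing": int(masked.mask.sum())}
                failed = True
            records.append({"site": site, "pool": pool, "sim": sim, "method": mc.name,
                            **errs, "failed": failed})
    return pd.DataFrame(records)
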