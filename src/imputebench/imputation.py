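"""Missing-value imputation methods behind a uniform interface.

Ten canonical configurations are benchmarked, spanning the classic families
for gene-expression matrices:

======  =======================================================
label   method
======  =======================================================
ROW     row (gene) average
KNN1    k-nearest neighbours, k = 1, Euclidean distance
KNN5    k-nearest neighbours, k = 5, Euclidean distance
SVD     iterative truncated-SVD (eigen gene) imputation
LLS1    local least squares, k = 1 neighbour
LLS3    local least squares, k = 3 neighbours
LLS4    local least squares, k = 4 neighbours
LSA     least squares adaptive (gene- and array-based blend)
BPCA    Bayesian PCA (variational, ARD prior)
NIPALS  PCA by NIPALS, inner products skipping missing cells
======  =======================================================

Every imputer takes a :class:`MaskedMatrix` and returns an
:class:`ImputedResult` whose values equal the input at every observed cell
and contain no missing cells.  Degenerate inputs fall back along
method -> row average -> global observed mean, with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

__all__ = [
    "MaskedMatrix",
    "MethodConfig",
    "ImputedResult",
    "canonical_method_configs",
    "impute",
    "impute_row_average",
    "impute_knn",
    "impute_svd",
    "impute_lls",
    "impute_lsa",
    "impute_bpca",
    "impute_nipals",
]

logger = logging.getLogger(__name__)

METHODS = ("ROW", "KNN", "SVD", "LSA", "LLS", "BPCA", "NIPALS")


@dataclass
class MaskedMatrix:
    """An expression matrix with missing entries flagged.

    ``values`` holds NaN at masked cells; ``mask`` is True where missing.
    ``truth`` (optional) stores the complete matrix in simulation contexts so
    imputations can be scored.
    """

    values: np.ndarray
    mask: np.ndarray
    truth: np.ndarray | None = None
    row_ids: list[str] | None = None
    col_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise InputError("values and mask dimensions disagree")
        if self.values.ndim != 2:
            raise InputError("MaskedMatrix must be 2-d")
        # NaN placement must agree with the mask
        self.values = np.where(self.mask, np.nan, self.values)
        obs = self.values[~self.mask]
        if obs.size and (np.any(~np.isfinite(obs)) or np.any(obs <= 0)):
            raise InputError("observed entries must be finite and strictly positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, truth: pd.DataFrame | None = None) -> "MaskedMatrix":
        values = df.to_numpy(dtype=float)
        return cls(values=values, mask=np.isnan(values),
                   truth=None if truth is None else truth.to_numpy(dtype=float),
                   row_ids=[str(i) for i in df.index],
                   col_ids=[str(c) for c in df.columns])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log_values(self) -> np.ndarray:
        """Natural-log view of the observed entries (NaN at masked cells)."""
        return np.log(self.values)


@dataclass(frozen=True)
class MethodConfig:
    """Configuration for one imputation run.

    ``convergence_threshold`` semantics differ per family: for SVD it is
    the per-iteration total change over the masked cells relative to their
    previous absolute sum (default 0.01); for BPCA it is relative to the
    observed value scale (default 1e-4); for NIPALS it bounds both the
    loading change and the imputed-value drift (default 1e-6).
    """

    method: str
    label: str | None = None
    k: int | None = None
    distance: str = "euclidean"
    n_components: int | None = None
    #: LLS neighbour space: "replicates" regresses the target column on its
    #: k most-correlated replicate columns over the probe-set rows (the
    #: classic small-S benchmark variant); "genes" regresses the target row
    #: on its k most-correlated gene rows
    lls_mode: str = "replicates"
    #: SVD update rule: "reconstruction" replaces missing cells with the
    #: rank-q truncated-SVD reconstruction (the classic R implementation);
    #: "regression" fits each incomplete row on the eigen genes restricted
    #: to its observed columns
    svd_mode: str = "reconstruction"
    convergence_threshold: float | None = None
    max_iter: int = 200
    lsa_n_genes: int = 10
    lsa_probe_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method.upper() not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.k is not None and self.k < 1:
            raise ConfigError("k must be a positive integer")
        if self.distance not in ("euclidean", "pearson"):
            raise ConfigError("distance must be 'euclidean' or 'pearson'")
        if self.lls_mode not in ("replicates", "genes"):
            raise ConfigError("lls_mode must be 'replicates' or 'genes'")
        if self.svd_mode not in ("reconstruction", "regression"):
            raise ConfigError("svd_mode must be 'reconstruction' or 'regression'")
        if self.n_components is not None and self.n_components < 1:
            raise ConfigError("n_components must be a positive integer")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be a positive integer")
        if not 0 < self.lsa_probe_fraction < 1:
            raise ConfigError("lsa_probe_fraction must lie in (0, 1)")
        if self.lsa_n_genes < 1:
            raise ConfigError("lsa_n_genes must be a positive integer")

    @property
    def name(self) -> str:
        return self.label or self.method.upper()


@dataclass
class ImputedResult:
    values: np.ndarray
    method_config: MethodConfig | None = None
    iterations_used: int = 0
    converged: bool = True

    def to_dataframe(self, m: MaskedMatrix) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=m.row_ids, columns=m.col_ids)


def canonical_method_configs(seed: int = 0) -> list[MethodConfig]:
    """The ten benchmark configurations, alphabetical by label."""
    return [
        MethodConfig(method="BPCA", label="BPCA", seed=seed),
        MethodConfig(method="KNN", label="KNN1", k=1, seed=seed),
        MethodConfig(method="KNN", label="KNN5", k=5, seed=seed),
        MethodConfig(method="LLS", label="LLS1", k=1, seed=seed),
        MethodConfig(method="LLS", label="LLS3", k=3, seed=seed),
        MethodConfig(method="LLS", label="LLS4", k=4, seed=seed),
        MethodConfig(method="LSA", label="LSA", seed=seed),
        MethodConfig(method="NIPALS", label="NIPALS", seed=seed),
        MethodConfig(method="ROW", label="ROW", seed=seed),
        MethodConfig(method="SVD", label="SVD", seed=seed),
    ]


# ---------------------------------------------------------------------------
# helpers


def _row_average_fill(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill masked cells with row means; fully-missing rows get the global mean."""
    if mask.all():
        raise InputError("matrix has no observed entries")
    out = X.copy()
    masked_nan = np.where(mask, np.nan, X)
    counts = (~mask).sum(axis=1)
    sums = np.where(mask, 0.0, X).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_means = np.where(counts > 0, sums / counts, np.nan)
    global_mean = np.nanmean(masked_nan)
    dead = np.isnan(row_means)
    if dead.any():
        logger.info("%d fully-missing row(s) filled with the global observed mean", dead.sum())
        row_means = np.where(dead, global_mean, row_means)
    rr, cc = np.nonzero(mask)
    out[rr, cc] = row_means[rr]
    return out


def _finish(m: MaskedMatrix, filled: np.ndarray, cfg: MethodConfig | None,
            iterations: int = 0, converged: bool = True) -> ImputedResult:
    out = m.values.copy()
    out[m.mask] = filled[m.mask]
    assert not np.isnan(out).any()
    return ImputedResult(values=out, method_config=cfg,
                         iterations_used=iterations, converged=converged)


# ---------------------------------------------------------------------------
# ROW


def impute_row_average(m: MaskedMatrix, cfg: MethodConfig | None = None) -> ImputedResult:
    """Replace each missing entry by the mean of its row's observed entries."""
    return _finish(m, _row_average_fill(m.values, m.mask), cfg)


# ---------------------------------------------------------------------------
# KNN


def impute_knn(m: MaskedMatrix, k: int, distance: str = "euclidean",
               cfg: MethodConfig | None = None) -> ImputedResult:
    """Average the k nearest neighbouring genes' values at the missing column.

    Distances are computed over the columns observed in both rows:
    root-mean-square difference (``euclidean``, normalised per coordinate so
    different overlap sizes compare fairly) or ``1 - |Pearson r|``.
    Candidates must be observed at the target column; if fewer than k exist
    all available are used; with none, the row average steps in.  Ties in
    distance break by row order.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    X, mask = m.values, m.mask
    G, S = X.shape
    fallback = _row_average_fill(X, mask)
    if G < 2:
        logger.warning("single-row matrix: KNN falls back to row average")
        return _finish(m, fallback, cfg)

    obs = ~mask
    X0 = np.where(mask, 0.0, X)
    filled = X.copy()
    for g in np.nonzero(mask.any(axis=1))[0]:
        overlap = obs & obs[g]                       # (G, S)
        n_ov = overlap.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            if distance == "euclidean":
                diff2 = ((X0[g] - X0) ** 2 * overlap).sum(axis=1)
                dist = np.sqrt(diff2 / n_ov)
            else:  # pearson
                n = n_ov.astype(float)
                sx = (X0[g] * overlap).sum(axis=1)
                sy = (X0 * overlap).sum(axis=1)
                sxx = (X0[g] ** 2 * overlap).sum(axis=1)
                syy = (X0 ** 2 * overlap).sum(axis=1)
                sxy = (X0[g] * X0 * overlap).sum(axis=1)
                denom = np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
                r = (n * sxy - sx * sy) / denom
                dist = 1.0 - np.abs(r)
        dist[g] = np.inf
        dist[n_ov == 0] = np.inf
        dist[~np.isfinite(dist)] = np.inf

        for s in np.nonzero(mask[g])[0]:
            ok = np.isfinite(dist) & obs[:, s]
            idx = np.nonzero(ok)[0]
            if idx.size == 0:
                filled[g, s] = fallback[g, s]
                continue
            order = idx[np.lexsort((idx, dist[idx]))]
            chosen = order[:k]
            if chosen.size < k:
                logger.info("row %d col %d: only %d KNN candidates (k=%d)",
                            g, s, chosen.size, k)
            filled[g, s] = X[chosen, s].mean()
    return _finish(m, filled, cfg)


# ---------------------------------------------------------------------------
# SVD


def _group_rows_by_pattern(mask: np.ndarray):
    """Yield (observed-col indices, missing-col indices, row indices) per
    distinct missing pattern among rows that have at least one missing cell."""
    rows = np.nonzero(mask.any(axis=1))[0]
    if rows.size == 0:
        return
    patterns, inverse = np.unique(mask[rows], axis=0, return_inverse=True)
    for p in range(patterns.shape[0]):
        pat = patterns[p]
        yield np.nonzero(~pat)[0], np.nonzero(pat)[0], rows[inverse == p]


def impute_svd(m: MaskedMatrix, n_components: int = 2, threshold: float = 0.01,
               max_iter: int = 200, mode: str = "reconstruction",
               cfg: MethodConfig | None = None, rcond: float = 0.1) -> ImputedResult:
    """EM-style SVD imputation on the leading eigen genes.

    Missing cells start at the row average and are re-estimated each
    iteration until the total absolute change over the masked cells,
    relative to their previous absolute sum, falls below ``threshold`` (the
    relative-change convention of the classic implementations; an absolute
    threshold is unreachable on raw intensity scales).

    ``mode="reconstruction"`` (default): missing cells are replaced by the
    rank-``n_components`` truncated-SVD reconstruction of the filled matrix
    — the stable variant used by the classic R implementation.

    ``mode="regression"``: each incomplete row's observed entries are
    regressed on the top right-singular vectors restricted to the observed
    columns and its missing entries re-estimated from the fit.  With only
    3-4 observed points per row the fit has unbounded leverage, so the
    pseudoinverse truncates singular directions below ``rcond`` of the
    leading one and per-iteration estimates are clipped to the observed
    dynamic range (runaway estimates would otherwise hijack an eigen gene
    on the next iteration).
    """
    X, mask = m.values, m.mask
    G, S = X.shape
    if not 1 <= n_components < min(G, S):
        raise ConfigError(f"n_components must satisfy 1 <= q < min(G, S) = {min(G, S)}")
    if mode not in ("reconstruction", "regression"):
        raise ConfigError("svd mode must be 'reconstruction' or 'regression'")
    if not mask.any():
        return ImputedResult(values=X.copy(), method_config=cfg, iterations_used=0, converged=True)

    filled = _row_average_fill(X, mask)
    lo, hi = X[~mask].min(), X[~mask].max()
    groups = list(_group_rows_by_pattern(mask))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if mode == "reconstruction":
            U, sv, Vt = np.linalg.svd(filled, full_matrices=False)
            recon = (U[:, :n_components] * sv[:n_components]) @ Vt[:n_components]
            new = filled.copy()
            new[mask] = recon[mask]
        else:
            _, _, Vt = np.linalg.svd(filled, full_matrices=False)
            E = Vt[:n_components]                    # (q, S) eigen genes
            new = filled.copy()
            for O, M, rows in groups:
                if O.size == 0:
                    continue  # fully-missing rows keep their row-average fill
                coef = np.linalg.pinv(E[:, O].T, rcond=rcond)  # (q, |O|)
                beta = coef @ X[np.ix_(rows, O)].T   # (q, n_rows)
                new[np.ix_(rows, M)] = np.clip((E[:, M].T @ beta).T, lo, hi)
        change = np.abs(new - filled)[mask].sum() / max(np.abs(filled)[mask].sum(), 1e-300)
        filled = new
        if change < threshold:
            converged = True
            break
    if not converged:
        logger.info("SVD imputation hit max_iter=%d without converging", max_iter)
    return _finish(m, filled, cfg, iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# LLS


def impute_lls(m: MaskedMatrix, k: int, mode: str = "replicates",
               cfg: MethodConfig | None = None, rcond: float = 1e-2) -> ImputedResult:
    """Local least squares imputation with k < S neighbours.

    ``mode="replicates"`` (default, the classic variant for matrices with a
    handful of replicate columns): each target column is regressed, without
    intercept, on its k most |Pearson|-correlated replicate columns over the
    rows observed in all of them — thousands of rows fitting k coefficients
    — and a missing cell is predicted from its row's values on those
    columns.

    ``mode="genes"``: the target gene row is regressed on its k most
    correlated gene rows (by |Pearson r| over the target's observed
    columns) and the missing columns are predicted from the fitted
    combination.  Neighbour candidates must be observed on every column the
    regression touches; the solve uses the pseudoinverse with
    rank-deficiency tolerance ``rcond`` — with only 3-4 observed columns the
    selected neighbours are near-collinear and singular directions below
    ``rcond`` of the leading one carry replicate noise, so they are
    truncated rather than inverted.
    """
    X, mask = m.values, m.mask
    G, S = X.shape
    if not 1 <= k < S:
        raise ConfigError(
            f"LLS requires k < number of columns (got k={k}, S={S}); "
            "the neighbour count must stay below the replicate count")
    if mode == "replicates":
        return _lls_replicates(m, k, cfg)
    return _lls_genes(m, k, cfg, rcond)


def _lls_replicates(m: MaskedMatrix, k: int, cfg: MethodConfig | None) -> ImputedResult:
    X, mask = m.values, m.mask
    G, S = X.shape
    fallback = _row_average_fill(X, mask)
    obs = ~mask
    filled = X.copy()
    # column-column correlations over rows observed in both
    corr = np.full((S, S), np.nan)
    for s in range(S):
        for t in range(s + 1, S):
            both = obs[:, s] & obs[:, t]
            if both.sum() >= 3:
                a, b = X[both, s], X[both, t]
                if a.var() > 0 and b.var() > 0:
                    corr[s, t] = corr[t, s] = np.corrcoef(a, b)[0, 1]
    for s in range(S):
        rows_missing = np.nonzero(mask[:, s])[0]
        if rows_missing.size == 0:
            continue
        r = corr[s]
        order = np.argsort(-np.abs(np.where(np.isfinite(r), r, -np.inf)), kind="stable")
        ranked = [t for t in order if t != s and np.isfinite(r[t])]
        if not ranked:
            filled[rows_missing, s] = fallback[rows_missing, s]
            logger.info("LLS column %d: no usable neighbour columns; row-average fallback", s)
            continue
        # group missing rows by their own observed columns; each group gets
        # the k best-ranked neighbour columns it actually has
        pat = obs[np.ix_(rows_missing, np.arange(S))]
        patterns, inverse = np.unique(pat, axis=0, return_inverse=True)
        for p in range(patterns.shape[0]):
            nb = [t for t in ranked if patterns[p][t]][:k]
            rows_p = rows_missing[inverse == p]
            if not nb:
                filled[rows_p, s] = fallback[rows_p, s]
                continue
            fit_rows = obs[:, s] & obs[:, nb].all(axis=1)
            if fit_rows.sum() < len(nb) + 1:
                filled[rows_p, s] = fallback[rows_p, s]
                continue
            A = X[np.ix_(np.nonzero(fit_rows)[0], nb)]
            b = X[fit_rows, s]
            coef, *_ = np.linalg.lstsq(A, b, rcond=None)
            filled[rows_p, s] = X[np.ix_(rows_p, nb)] @ coef
    return _finish(m, filled, cfg)


def _lls_genes(m: MaskedMatrix, k: int, cfg: MethodConfig | None,
               rcond: float) -> ImputedResult:
    X, mask = m.values, m.mask
    G, S = X.shape
    fallback = _row_average_fill(X, mask)
    complete = ~mask.any(axis=1)
    filled = X.copy()
    for g in np.nonzero(mask.any(axis=1))[0]:
        O = np.nonzero(~mask[g])[0]
        M = np.nonzero(mask[g])[0]
        cand = np.nonzero(complete)[0]
        cand = cand[cand != g]
        if O.size < 2 or cand.size == 0:
            filled[g, M] = fallback[g, M]
            logger.info("LLS row %d: no usable neighbours; row-average fallback", g)
            continue
        w = X[g, O]
        C = X[np.ix_(cand, O)]
        wc = w - w.mean()
        Cc = C - C.mean(axis=1, keepdims=True)
        denom = np.sqrt((wc**2).sum()) * np.sqrt((Cc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Cc @ wc) / denom
        valid = np.isfinite(r)
        if not valid.any():
            filled[g, M] = fallback[g, M]
            logger.info("LLS row %d: all correlations undefined; row-average fallback", g)
            continue
        cand, r = cand[valid], r[valid]
        order = np.lexsort((cand, -np.abs(r)))
        sel = cand[order[:k]]
        A = X[np.ix_(sel, O)]                        # (k', |O|)
        coef = np.linalg.pinv(A.T, rcond=rcond) @ w  # (k',)
        filled[g, M] = X[np.ix_(sel, M)].T @ coef
    return _finish(m, filled, cfg)


# ---------------------------------------------------------------------------
# LSA


def _lsa_column_models(W: np.ndarray) -> dict[tuple[int, int], tuple[float, float, float]]:
    """Per ordered column pair (s, t): intercept, slope and correlation of
    regressing column s on column t over rows observed in both."""
    S = W.shape[1]
    models: dict[tuple[int, int], tuple[float, float, float]] = {}
    obs = ~np.isnan(W)
    for s in range(S):
        for t in range(S):
            if s == t:
                continue
            both = obs[:, s] & obs[:, t]
            if both.sum() < 3:
                continue
            y, x = W[both, s], W[both, t]
            vx = x.var()
            if vx <= 0 or y.var() <= 0:
                continue
            b = ((x - x.mean()) * (y - y.mean())).mean() / vx
            a = y.mean() - b * x.mean()
            r = np.corrcoef(x, y)[0, 1]
            models[(s, t)] = (a, b, r)
    return models


def _lsa_estimates(W: np.ndarray, cells: np.ndarray, n_genes: int):
    """Gene- and array-based estimates (and neighbour-correlation strength)
    for the given (row, col) cells of a working matrix W (NaN = missing)."""
    G, S = W.shape
    obs = ~np.isnan(W)
    complete = obs.all(axis=1)
    comp_idx = np.nonzero(complete)[0]
    col_models = _lsa_column_models(W)
    weight = lambda r: (r**2 / (1.0 - r**2 + 1e-6)) ** 2

    gene_est = np.full(len(cells), np.nan)
    arr_est = np.full(len(cells), np.nan)
    rstar = np.full(len(cells), np.nan)

    # group target cells by row so each row's neighbourhood is computed once
    by_row: dict[int, list[int]] = {}
    for i, (g, s) in enumerate(cells):
        by_row.setdefault(int(g), []).append(i)

    for g, cell_idx in by_row.items():
        O = np.nonzero(obs[g])[0]
        cand = comp_idx[comp_idx != g]
        if O.size >= 3 and cand.size > 0:
            y = W[g, O]
            C = W[np.ix_(cand, O)]
            yc = y - y.mean()
            Cc = C - C.mean(axis=1, keepdims=True)
            denom = np.sqrt((yc**2).sum()) * np.sqrt((Cc**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (Cc @ yc) / denom
            valid = np.isfinite(r) & (np.abs(r) < 1.0 - 1e-12)
            # keep exactly-correlated neighbours too, with capped weight
            exact = np.isfinite(r) & ~valid
            r = np.where(exact, np.sign(r) * (1.0 - 1e-9), r)
            valid |= exact
            if valid.any():
                cvag, rv = cand[valid], r[valid]
                order = np.lexsort((cvag, -np.abs(rv)))[:n_genes]
                sel, rsel = cvag[order], rv[order]
                # univariate fits of target on each neighbour over O
                Xn = W[np.ix_(sel, O)]
                xm = Xn.mean(axis=1)
                vx = Xn.var(axis=1)
                cov = ((Xn - xm[:, None]) * yc).mean(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    slope = np.where(vx > 0, cov / np.maximum(vx, 1e-300), 0.0)
                intercept = y.mean() - slope * xm
                ws = weight(np.clip(np.abs(rsel), 0, 1 - 1e-9))
                for i in cell_idx:
                    s = int(cells[i][1])
                    preds = intercept + slope * W[sel, s]
                    ok = np.isfinite(preds)
                    if ok.any() and ws[ok].sum() > 0:
                        gene_est[i] = float((ws[ok] * preds[ok]).sum() / ws[ok].sum())
                        rstar[i] = float(np.abs(rsel).max())
        for i in cell_idx:
            s = int(cells[i][1])
            preds, wts = [], []
            for t in np.nonzero(obs[g])[0]:
                key = (s, int(t))
                if key in col_models:
                    a, b, r_st = col_models[key]
                    preds.append(a + b * W[g, t])
                    wts.append(weight(r_st))
            if preds and sum(wts) > 0:
                arr_est[i] = float(np.dot(wts, preds) / sum(wts))
    return gene_est, arr_est, rstar


def impute_lsa(m: MaskedMatrix, cfg: MethodConfig) -> ImputedResult:
    """Least squares adaptive: blend gene-based and array-based regression
    estimates with weights tuned on a held-out probe of observed cells.

    The probe cells (a seeded random fraction of the observed entries) are
    masked additionally; both estimates and their errors there calibrate, per
    quartile bin of neighbour-correlation strength r*, the mixing weight p
    minimising the squared blend error (closed form, clipped to [0, 1]).
    """
    X, mask = m.values, m.mask
    G, S = X.shape
    if S < 3:
        raise ConfigError("LSA requires at least 3 columns")
    fallback = _row_average_fill(X, mask)
    missing_cells = np.argwhere(mask)
    if missing_cells.size == 0:
        return ImputedResult(values=X.copy(), method_config=cfg, iterations_used=0)

    rng = np.random.default_rng(cfg.seed)
    obs_cells = np.argwhere(~mask)
    n_probe = max(4, int(round(cfg.lsa_probe_fraction * len(obs_cells))))
    n_probe = min(n_probe, len(obs_cells) - 1)
    probe_cells = obs_cells[rng.choice(len(obs_cells), size=n_probe, replace=False)]

    W_aug = X.copy()
    W_aug[probe_cells[:, 0], probe_cells[:, 1]] = np.nan
    ge_p, ae_p, rs_p = _lsa_estimates(W_aug, probe_cells, cfg.lsa_n_genes)
    truth_p = X[probe_cells[:, 0], probe_cells[:, 1]]

    # calibrate p per quartile bin of r* on probe cells with both estimates
    both = np.isfinite(ge_p) & np.isfinite(ae_p) & np.isfinite(rs_p)
    if both.sum() >= 8:
        edges = np.quantile(rs_p[both], [0.25, 0.5, 0.75])
    else:
        edges = np.array([])
    n_bins = len(edges) + 1
    p_bins = np.full(n_bins, 0.5)
    if both.any():
        bins = np.searchsorted(edges, rs_p[both])
        a, b, y = ge_p[both], ae_p[both], truth_p[both]
        for bi in range(n_bins):
            sel = bins == bi
            if not sel.any():
                continue
            d = a[sel] - b[sel]
            den = (d**2).sum()
            p_bins[bi] = float(np.clip(((y[sel] - b[sel]) * d).sum() / den, 0, 1)) if den > 0 else 0.5

    ge, ae, rs = _lsa_estimates(X.copy(), missing_cells, cfg.lsa_n_genes)
    filled = X.copy()
    for i, (g, s) in enumerate(missing_cells):
        has_g, has_a = np.isfinite(ge[i]), np.isfinite(ae[i])
        if has_g and has_a:
            bi = int(np.searchsorted(edges, rs[i])) if len(edges) else 0
            p = p_bins[bi]
            filled[g, s] = p * ge[i] + (1 - p) * ae[i]
        elif has_g:
            filled[g, s] = ge[i]
        elif has_a:
            filled[g, s] = ae[i]
        else:
            filled[g, s] = fallback[g, s]
            logger.info("LSA cell (%d, %d): no estimate computable; row-average fallback", g, s)
    return _finish(m, filled, cfg)


# ---------------------------------------------------------------------------
# BPCA


def impute_bpca(m: MaskedMatrix, n_components: int | None = None, max_iter: int = 200,
                tol: float = 1e-4, seed: int = 0, cfg: MethodConfig | None = None) -> ImputedResult:
    """Variational Bayesian PCA with an automatic-relevance-determination
    prior; missing entries are replaced by their posterior mean.

    The model is ``y = W x + mu + eps`` with isotropic Gaussian noise; ARD
    hyper-parameters (one precision per column of W) shrink unneeded
    components, so ``n_components`` defaults to S - 1 and the effective rank
    is learned.  Initialisation is the SVD of the row-average-filled matrix
    plus seeded jitter; the run is deterministic given the seed.
    """
    X, mask = m.values, m.mask
    G, S = X.shape
    q = n_components if n_components is not None else max(1, S - 1)
    if not 1 <= q <= S - 1:
        raise ConfigError(f"n_components must satisfy 1 <= q <= S-1 = {S - 1}")
    if not mask.any():
        return ImputedResult(values=X.copy(), method_config=cfg, iterations_used=0, converged=True)

    rng = np.random.default_rng(seed)
    filled = _row_average_fill(X, mask)
    scale = float(np.abs(X[~mask]).mean())
    tol_abs = tol * scale

    mu = filled.mean(axis=0)
    C = filled - mu
    U, sv, Vt = np.linalg.svd(C, full_matrices=False)
    W = Vt[:q].T * (sv[:q] / np.sqrt(G))
    W = W + 1e-3 * scale * rng.standard_normal(W.shape)
    resid = C - (U[:, :q] * sv[:q]) @ Vt[:q]
    tau = 1.0 / max(resid.var(), 1e-12 * scale**2 + 1e-300)
    alpha = np.ones(q)

    groups = list(_group_rows_by_pattern(mask))
    Y = filled
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Xs = np.zeros((G, q))
        Sxx_cov = np.zeros((q, q))
        # complete rows in one shot
        comp = ~mask.any(axis=1)
        if comp.any():
            P = np.eye(q) + tau * (W.T @ W)
            Sigma = np.linalg.inv(P)
            Mcoef = tau * Sigma @ W.T
            Xs[comp] = (Y[comp] - mu) @ Mcoef.T
            Sxx_cov += comp.sum() * Sigma
        Ynew = np.where(mask, 0.0, X)
        for O, Mi, rows in groups:
            Wo = W[O]
            P = np.eye(q) + tau * (Wo.T @ Wo)
            Sigma = np.linalg.inv(P)
            Mcoef = tau * Sigma @ Wo.T
            xs = (Y[np.ix_(rows, O)] - mu[O]) @ Mcoef.T if O.size else np.zeros((rows.size, q))
            Xs[rows] = xs
            Sxx_cov += rows.size * Sigma
            Ynew[np.ix_(rows, Mi)] = xs @ W[Mi].T + mu[Mi]
        Ynew[~mask] = X[~mask]

        delta = np.abs(Ynew - Y)[mask].max() if mask.any() else 0.0
        Y = Ynew
        mu = Y.mean(axis=0)
        Yc = Y - mu
        Sxx = Xs.T @ Xs + Sxx_cov
        Sxy = Xs.T @ Yc                              # (q, S)
        W = Sxy.T @ np.linalg.inv(Sxx + np.diag(alpha) / tau)
        alpha = S / (np.sum(W**2, axis=0) + 1e-10)
        sq = (Yc**2).sum() - 2 * np.trace(W.T @ Sxy.T) + np.trace((W.T @ W) @ Sxx)
        tau = G * S / max(sq, 1e-12 * scale**2 * G * S + 1e-300)
        if delta < tol_abs and it > 1:
            converged = True
            break
    if not converged:
        logger.info("BPCA hit max_iter=%d without converging", max_iter)
    return _finish(m, Y, cfg, iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# NIPALS


def _nipals_pass(X: np.ndarray, mask: np.ndarray, mu: np.ndarray, n_components: int,
                 max_iter: int, tol: float) -> tuple[np.ndarray, bool, int]:
    """One skip-missing NIPALS fit around the given column means; returns the
    reconstruction ``mu + sum_a t_a p_a^T``, a convergence flag and the
    iteration count."""
    G, _ = X.shape
    obs = (~mask).astype(float)
    A = np.where(mask, 0.0, X - mu)
    recon = np.tile(mu, (G, 1))
    converged = True
    total_iters = 0
    for _ in range(n_components):
        var = (A**2).sum(axis=0)
        t = A[:, int(np.argmax(var))].copy()
        if not np.any(t):
            logger.warning("NIPALS: degenerate residual; stopping at mean reconstruction")
            break
        p = np.zeros(X.shape[1])
        comp_ok = False
        for _ in range(max_iter):
            total_iters += 1
            denom_p = obs.T @ (t * t)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(denom_p > 0, (A.T @ t) / denom_p, 0.0)
            norm = np.linalg.norm(p)
            if norm == 0:
                break
            p /= norm
            denom_t = obs @ (p * p)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_new = np.where(denom_t > 0, (A @ p) / denom_t, 0.0)
            if np.linalg.norm(t_new - t) <= tol * (np.linalg.norm(t_new) + 1e-300):
                t = t_new
                comp_ok = True
                break
            t = t_new
        if not comp_ok:
            logger.warning("NIPALS component failed to converge; accepting current vectors")
            converged = False
        recon += np.outer(t, p)
        A -= np.where(mask, 0.0, np.outer(t, p))
    return recon, converged, total_iters


def impute_nipals(m: MaskedMatrix, n_components: int = 2, max_iter: int = 500,
                  tol: float = 1e-6, cfg: MethodConfig | None = None) -> ImputedResult:
    """NIPALS PCA that skips missing cells in every inner product.

    Columns are mean-centred; each component is extracted by alternating
    score/loading regressions over the available cells, then deflated, and
    missing entries are reconstructed as ``mean + sum_a t_a p_a^T``.  Because
    column means computed on observed cells alone are biased by the missing
    rows, the mean is refined in an outer loop: means are recomputed from the
    current filled matrix and the fit repeated until the imputed values
    stabilise (relative change below ``tol``).
    """
    X, mask = m.values, m.mask
    G, S = X.shape
    if not 1 <= n_components <= min(G, S):
        raise ConfigError(f"n_components must satisfy 1 <= q <= min(G, S) = {min(G, S)}")
    if mask.all():
        raise InputError("matrix has no observed entries")

    with np.errstate(invalid="ignore"):
        mu = np.nanmean(np.where(mask, np.nan, X), axis=0)
    mu = np.where(np.isnan(mu), np.nanmean(X[~mask]), mu)
    scale = float(np.abs(X[~mask]).mean()) + 1e-300

    recon = np.tile(mu, (G, 1))
    converged = True
    total_iters = 0
    filled = np.where(mask, recon, X)
    for _ in range(50):
        recon, conv, iters = _nipals_pass(X, mask, mu, n_components, max_iter, tol)
        converged = conv
        total_iters += iters
        new_filled = np.where(mask, recon, X)
        delta = np.abs(new_filled - filled)[mask].max() if mask.any() else 0.0
        filled = new_filled
        mu = filled.mean(axis=0)
        if delta <= tol * scale:
            break
    return _finish(m, recon, cfg, iterations=total_iters, converged=converged)


# ---------------------------------------------------------------------------
# dispatch


def impute(m: MaskedMatrix, cfg: MethodConfig) -> ImputedResult:
    """Dispatch to the configured method; output is complete and equals the
    input at every observed cell."""
    method = cfg.method.upper()
    S = m.shape[1]
    if method == "ROW":
        return impute_row_average(m, cfg)
    if method == "KNN":
        return impute_knn(m, k=cfg.k or 1, distance=cfg.distance, cfg=cfg)
    if method == "SVD":
        return impute_svd(m, n_components=cfg.n_components or 2,
                          threshold=cfg.convergence_threshold if cfg.convergence_threshold is not None else 0.01,
                          max_iter=cfg.max_iter, mode=cfg.svd_mode, cfg=cfg)
    if method == "LLS":
        return impute_lls(m, k=cfg.k or 1, mode=cfg.lls_mode, cfg=cfg)
    if method == "LSA":
        return impute_lsa(m, cfg)
    if method == "BPCA":
        return impute_bpca(m, n_components=cfg.n_components, max_iter=cfg.max_iter,
                           tol=cfg.convergence_threshold if cfg.convergence_threshold is not None else 1e-4,
                           seed=cfg.seed, cfg=cfg)
    if method == "NIPALS":
        return impute_nipals(m, n_components=cfg.n_components or 2, max_iter=cfg.max_iter,
                             tol=cfg.convergence_threshold if cfg.convergence_threshold is not None else 1e-6,
                             cfg=cfg)
    raise ConfigError(f"unknown method {cfg.method!r}")
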