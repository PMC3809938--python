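"""Seeded synthetic probe-level data with the MAQC factorial structure.

The MAQC reference study hybridised two reference RNAs — Universal Human
Reference RNA (UHRR) and Human Brain Reference RNA (HBRR) — and two linear
mixtures of them (75/25 and 25/75) at six laboratory sites with five
replicate arrays per site x pool cell.  This module emulates that design at
the probe level so the whole detection -> filtering -> summarisation ->
imputation pipeline can be exercised without any download:

* each probe set carries 11-20 probe pairs (PM/MM) with fixed per-probe
  affinities,
* latent linear-scale expression is drawn once per probe set for each
  reference; pools mix the two references linearly *before* any noise is
  applied, because the pools are physical RNA mixtures,
* site effects and replicate noise are multiplicative log-normal,
* MM probes receive a cross-talk fraction of the true signal on top of a
  shared background, which keeps PM > MM in expectation for expressed genes.

A shortcut generator (:func:`generate_expression_matrix`) produces a
complete positive expression matrix for a single site x pool cell with
block-correlated gene clusters; it skips the probe level entirely and exists
for fast imputation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

__all__ = ["GeneratorConfig", "ProbeLevelTable", "generate_dataset", "generate_expression_matrix"]

DEFAULT_POOLS = {"A": 1.0, "B": 0.0, "C": 0.75, "D": 0.25}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic probe-level generator.

    The defaults emulate the reference design: 6 sites x 4 pools x 5
    replicates, probe sets of 11-20 probe pairs, and expressed fractions
    chosen so that downstream percent-present lands in the low-to-mid 50s.
    """

    n_probe_sets: int = 500
    n_sites: int = 6
    n_replicates: int = 5
    pool_mixtures: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_POOLS))
    probes_per_set_range: tuple[int, int] = (11, 20)
    frac_expressed_uhrr: float = 0.54
    frac_expressed_hbrr: float = 0.52
    #: Gaussian-copula correlation between the two references' expressed
    #: indicator; high overlap mimics two human transcriptomes and keeps the
    #: mixture pools' percent-present close to the pure pools'.
    expressed_correlation: float = 0.97
    #: natural-log location/scale of the latent linear-scale expression
    signal_log_mean: float = 5.5
    signal_log_sd: float = 1.2
    site_effect_sd: float = 0.10
    replicate_cv: float = 0.08
    #: per-observation multiplicative measurement noise (log-sd)
    probe_noise_cv: float = 0.08
    #: log-sd of fixed per-probe affinities
    affinity_sd: float = 0.40
    mm_crosstalk: float = 0.30
    noise_floor: float = 50.0
    #: shortcut expression-matrix generator: number of correlated gene
    #: clusters (None -> one cluster per ~4 genes, emulating multiple probe
    #: sets per transcript) and the within-cluster correlation of replicate
    #: noise
    n_clusters: int | None = None
    block_correlation: float = 0.95
    #: shared per-array (column) log-scale effects, expressed as a multiple
    #: of replicate_cv; gene sensitivity to them grows with log-intensity
    #: (slope per standard deviation of log signal) — bright genes feel
    #: hybridisation/labelling/scanner drift more than dim ones
    array_effect_weight: float = 1.0
    array_sensitivity_slope: float = 0.5
    #: spread of gene-to-gene sensitivity differences beyond the intensity
    #: trend (sequence-dependent hybridisation response)
    sensitivity_diversity: float = 0.3
    #: multiplier of the extra relative noise dim genes carry; per-gene
    #: log-noise sd is replicate_cv * (1 + low_intensity_noise *
    #: noise_floor / (noise_floor + signal)), the classic variance-mean
    #: relationship
    low_intensity_noise: float = 10.0
    #: lower truncation of the latent expression scale in the shortcut
    #: matrix generator: it emulates a post-filter complete matrix, which
    #: contains only transcripts detected in every replicate, so rows below
    #: the detection limit do not occur
    expression_floor: float = 100.0
    #: heavy-tailed cell contamination: fraction of cells hit by a localised
    #: artifact (dust, scratch, bright speck) and the log-sd of its
    #: multiplicative size — the very defects that make imputation necessary
    outlier_fraction: float = 0.0
    outlier_log_sd: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_probe_sets < 1:
            raise ConfigError("n_probe_sets must be a positive integer")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be a positive integer")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be a positive integer")
        if not self.pool_mixtures:
            raise ConfigError("pool_mixtures must be nonempty")
        for label, mix in self.pool_mixtures.items():
            if not 0.0 <= mix <= 1.0:
                raise ConfigError(f"pool_mixtures[{label!r}] must lie in [0, 1]")
        lo, hi = self.probes_per_set_range
        if not (11 <= lo <= hi <= 20):
            raise ConfigError("probes_per_set_range must lie within [11, 20]")
        for name in ("frac_expressed_uhrr", "frac_expressed_hbrr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not -1.0 < self.expressed_correlation < 1.0:
            raise ConfigError("expressed_correlation must lie in (-1, 1)")
        if not 0.0 <= self.mm_crosstalk < 1.0:
            raise ConfigError("mm_crosstalk must lie in [0, 1)")
        if self.noise_floor <= 0:
            raise ConfigError("noise_floor must be positive")
        for name in ("signal_log_sd", "site_effect_sd", "replicate_cv",
                     "probe_noise_cv", "affinity_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ConfigError("n_clusters must be a positive integer or None")
        if not 0.0 <= self.block_correlation <= 1.0:
            raise ConfigError("block_correlation must lie in [0, 1]")
        if self.array_effect_weight < 0 or self.array_sensitivity_slope < 0 \
                or self.sensitivity_diversity < 0 or self.low_intensity_noise < 0:
            raise ConfigError("array-effect and noise parameters must be nonnegative")
        if self.expression_floor <= 0:
            raise ConfigError("expression_floor must be positive")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigError("outlier_fraction must lie in [0, 1)")
        if self.outlier_log_sd < 0:
            raise ConfigError("outlier_log_sd must be nonnegative")

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class ProbeLevelTable:
    """Long-format PM/MM intensities plus the sample sheet.

    ``probes`` has columns ``probe_set_id, probe_pair_index, sample_id, pm,
    mm``; ``samples`` has ``sample_id, site, pool, replicate``.  ``latents``
    stores the linear-scale latent signal per probe set per pool (index =
    probe_set_id, columns = pool labels) for generator-level checks; it is
    not part of the on-disk contract.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    latents: pd.DataFrame | None = None

    @property
    def probe_set_ids(self) -> list[str]:
        return list(dict.fromkeys(self.probes["probe_set_id"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])


def _expressed_flags(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Correlated Bernoulli expressed/unexpressed flags via a Gaussian copula."""
    g = cfg.n_probe_sets
    rho = cfg.expressed_correlation
    shared = rng.standard_normal(g)
    z1 = rho * shared + np.sqrt(1 - rho**2) * rng.standard_normal(g)
    z2 = rho * shared + np.sqrt(1 - rho**2) * rng.standard_normal(g)
    expr_u = z1 < stats.norm.ppf(cfg.frac_expressed_uhrr)
    expr_h = z2 < stats.norm.ppf(cfg.frac_expressed_hbrr)
    return expr_u, expr_h


def generate_dataset(config: GeneratorConfig) -> ProbeLevelTable:
    """Generate a complete probe-level dataset under the factorial design.

    Latent linear-scale expression is drawn once per probe set for each
    reference (zero when unexpressed); pool ``p`` gets
    ``mix_p * UHRR + (1 - mix_p) * HBRR`` on the linear scale.  Per-site and
    per-replicate multiplicative log-normal factors are then applied, and

    ``PM = (noise_floor * b + a * signal) * e``,
    ``MM = (noise_floor * b' + crosstalk * a * signal) * e'``

    with per-probe affinities ``a`` and backgrounds ``b, b'`` fixed across
    samples, and ``e, e'`` i.i.d. log-normal measurement noise.  Everything
    is strictly positive and bit-for-bit reproducible from the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.n_probe_sets
    pools = list(config.pool_mixtures)

    # probe-set structure: 11-20 probe pairs, fixed across samples
    lo, hi = config.probes_per_set_range
    n_pairs = rng.integers(lo, hi + 1, size=g)
    ps_ids = np.array([f"PS{i:05d}" for i in range(1, g + 1)])

    # latent linear-scale expression per reference
    expr_u, expr_h = _expressed_flags(config, rng)
    base_u = np.exp(rng.normal(config.signal_log_mean, config.signal_log_sd, g))
    base_h = np.exp(rng.normal(config.signal_log_mean, config.signal_log_sd, g))
    latent_u = np.where(expr_u, base_u, 0.0)
    latent_h = np.where(expr_h, base_h, 0.0)

    # pools are physical mixtures: mix on the linear scale, before any noise
    latent = {p: m * latent_u + (1 - m) * latent_h for p, m in config.pool_mixtures.items()}
    latents = pd.DataFrame(latent, index=ps_ids)
    latents["UHRR"] = latent_u
    latents["HBRR"] = latent_h

    # per-probe constants
    total_probes = int(n_pairs.sum())
    affinity = np.exp(rng.normal(0.0, config.affinity_sd, total_probes))
    bg_pm = np.exp(rng.normal(0.0, 0.10, total_probes))
    bg_mm = np.exp(rng.normal(0.0, 0.10, total_probes))
    probe_to_set = np.repeat(np.arange(g), n_pairs)
    pair_index = np.concatenate([np.arange(1, n + 1) for n in n_pairs])

    # site effects: per (site, probe set)
    site_eff = np.exp(rng.normal(0.0, config.site_effect_sd, (config.n_sites, g)))

    samples = []
    frames = []
    for si in range(config.n_sites):
        site = f"site{si + 1}"
        for pool in pools:
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{site}_{pool}_r{rep}"
                samples.append((sample_id, site, pool, rep))
                rep_noise = np.exp(rng.normal(0.0, config.replicate_cv, g))
                signal_set = latent[pool] * site_eff[si] * rep_noise
                signal = signal_set[probe_to_set]
                e_pm = np.exp(rng.normal(0.0, config.probe_noise_cv, total_probes))
                e_mm = np.exp(rng.normal(0.0, config.probe_noise_cv, total_probes))
                pm = (config.noise_floor * bg_pm + affinity * signal) * e_pm
                mm = (config.noise_floor * bg_mm + config.mm_crosstalk * affinity * signal) * e_mm
                frames.append(pd.DataFrame({
                    "probe_set_id": ps_ids[probe_to_set],
                    "probe_pair_index": pair_index,
                    "sample_id": sample_id,
                    "pm": pm,
                    "mm": mm,
                }))

    probes = pd.concat(frames, ignore_index=True)
    sheet = pd.DataFrame(samples, columns=["sample_id", "site", "pool", "replicate"])
    return ProbeLevelTable(probes=probes, samples=sheet, latents=latents)


def generate_expression_matrix(config: GeneratorConfig, site: str = "site1",
                               pool: str = "A") -> pd.DataFrame:
    """Complete positive G x S expression matrix for one site x pool cell.

    Three layers of technical variation on the log scale:

    * shared per-array (column) effects whose per-gene sensitivity grows
      with log-intensity (``array_effect_weight``,
      ``array_sensitivity_slope``) — the global hybridisation/labelling/
      scanner variation that makes replicate arrays move together, felt most
      by bright genes;
    * cluster-correlated replicate noise: within a cluster the noise shares
      a common component with weight ``block_correlation``, so at
      correlation 1 rows of a cluster are exactly proportional — clusters
      emulate multiple probe sets measuring the same transcript;
    * independent per-cell noise, inflated for dim genes by the
      variance-mean relationship (``low_intensity_noise``).

    Every layer scales with ``replicate_cv``: at ``replicate_cv = 0`` all
    replicate columns are exactly equal.

    Skips the probe level entirely; intended for imputation unit tests and
    scaled-down benchmarks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g, s = config.n_probe_sets, config.n_replicates
    n_clusters = config.n_clusters if config.n_clusters is not None else max(1, g // 4)

    # latent scale: log-normal truncated below at the detection limit — a
    # post-filter matrix holds only transcripts present in every replicate
    a = (np.log(config.expression_floor) - config.signal_log_mean) / config.signal_log_sd
    log_scale = (config.signal_log_mean + config.signal_log_sd
                 * stats.truncnorm.ppf(rng.uniform(size=g), a, np.inf))
    scale = np.exp(log_scale)
    clusters = rng.integers(0, n_clusters, size=g)
    z_cluster = rng.standard_normal((n_clusters, s))
    z_own = rng.standard_normal((g, s))
    w = config.block_correlation
    # per-array effect, sensitivity rising with log-intensity; probe sets of
    # one transcript (a cluster) share the transcript's sensitivity
    array_effect = config.array_effect_weight * rng.standard_normal(s)
    cluster_mean_logscale = np.bincount(clusters, weights=log_scale, minlength=n_clusters)
    cluster_size = np.maximum(np.bincount(clusters, minlength=n_clusters), 1)
    z = ((cluster_mean_logscale / cluster_size)[clusters]
         - config.signal_log_mean) / max(config.signal_log_sd, 1e-12)
    z_div = rng.standard_normal(n_clusters)[clusters]
    sensitivity = np.maximum(1.0 + config.array_sensitivity_slope * z
                             + config.sensitivity_diversity * z_div, 0.0)
    # dim genes carry extra relative noise (variance-mean relationship)
    noise_infl = 1.0 + config.low_intensity_noise * config.noise_floor / (config.noise_floor + scale)
    log_noise = config.replicate_cv * (
        sensitivity[:, None] * array_effect[None, :]
        + noise_infl[:, None] * (np.sqrt(w) * z_cluster[clusters]
                                 + np.sqrt(1 - w) * z_own))
    # localised artifacts (dust, scratches): rare cells with large
    # multiplicative distortion, independent of everything else
    hit = rng.uniform(size=(g, s)) < config.outlier_fraction
    log_noise = log_noise + np.where(
        hit, rng.normal(0.0, config.outlier_log_sd, (g, s)), 0.0)
    values = scale[:, None] * np.exp(log_noise)

    ids = [f"PS{i:05d}" for i in range(1, g + 1)]
    cols = [f"{site}_{pool}_r{r}" for r in range(1, s + 1)]
    return pd.DataFrame(values, index=ids, columns=cols)
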