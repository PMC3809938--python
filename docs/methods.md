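# Methods

`imputebench` reproduces, on synthetic data, the classic study design for
comparing missing-value imputation methods on Affymetrix-style expression
arrays: build complete expression matrices from technical-replicate arrays,
delete entries at random, impute them with ten methods, and score the
imputations with four error measures aggregated into ranks. This note
documents the models, algorithms, defaults and design choices, and what the
synthetic data does and does not establish about real arrays.

## Study design

The emulated design is the MAQC reference layout: two reference RNAs —
Universal Human Reference RNA (UHRR) and Human Brain Reference RNA (HBRR) —
and two physical mixtures of them (pool A = 100% UHRR, B = 100% HBRR,
C = 75/25, D = 25/75), assayed at 6 laboratory sites with 5 replicate
arrays per site × pool, i.e. 120 arrays and 24 site × pool cells. Each cell
is analysed separately: detection calls are made per array, probe sets
Present in **all five** replicates of the cell are retained, and the
retained rows form that cell's complete matrix `CD` (genes × 5 replicates).

## Synthetic probe-level data

The probe-level generator draws, per probe set *g*:

* a number of PM/MM probe pairs, uniform on [11, 20], fixed across arrays;
* expressed/unexpressed indicators for UHRR and HBRR from a Gaussian copula
  with correlation 0.97 and marginal expressed fractions 0.54 / 0.52 —
  the high overlap reflects two human transcriptomes sharing most expressed
  genes, and it keeps percent-present similar across pools (a mixture pool
  expresses the union of its components);
* latent linear-scale abundance per reference, log-normal with natural-log
  location 5.5 and scale 1.2 (median ≈ 245 intensity units); unexpressed
  means exactly zero.

Pool abundances are **linear** mixtures of the two references, mixed before
any noise, because the pools are physical RNA mixtures. Technical layers
are multiplicative log-normal: per-site × probe-set effects (log-sd 0.10),
per-replicate noise (log-sd `replicate_cv` = 0.08) and per-observation
probe noise (log-sd 0.08). Probe intensities are

    PM = (floor·b + a·signal) · e,     MM = (floor·b' + 0.3·a·signal) · e',

with fixed per-probe affinities `a` (log-sd 0.4), fixed iid backgrounds
`b, b'` around the noise floor of 50, and iid measurement noise `e, e'`.
The MM cross-talk fraction 0.3 guarantees PM > MM in expectation for
expressed probe sets, so detection calls behave; for unexpressed probe sets
PM and MM are exchangeable and the median discrimination score is 0.

With these defaults the percent-present of the synthetic arrays falls in
the low-to-mid 50s with pool B lowest — the regime reported for real
reference-RNA arrays.

## Shortcut matrix generator

Imputation experiments need many complete matrices quickly, so a second
generator emulates one site × pool cell's **post-filter** matrix directly
(G genes × 5 replicates), skipping the probe level. Its structure encodes
four facts about technical-replicate arrays:

1. **Truncated dynamic range.** Latent gene scales are log-normal
   (location 5.5, scale 1.2) truncated below at 100 intensity units: a
   post-filter matrix contains only transcripts detected in every
   replicate, so rows below the detection limit do not occur.
2. **Shared array effects.** Each replicate array carries a global
   log-scale effect (sd = `array_effect_weight` × `replicate_cv`); a gene's
   sensitivity to it rises with log-intensity (slope 0.5 per sd of log
   signal) plus a transcript-specific component (sd 0.3) shared by all
   probe sets of a transcript. This is the hybridisation/labelling/scanner
   drift that makes replicate arrays move together, felt most by bright
   genes.
3. **Cluster structure.** Genes fall into clusters of ~4 (multiple probe
   sets measuring one transcript); within a cluster the replicate noise
   shares a common component with weight 0.95, so cluster rows are nearly
   proportional.
4. **Variance–mean relationship.** The per-gene log-noise sd is
   `replicate_cv · (1 + 10·floor/(floor + signal))`: dim genes carry several
   times the relative noise of bright ones, the standard microarray noise
   profile.

An optional heavy-tailed cell-contamination layer (dust/scratch artifacts)
exists but defaults off: gross artifacts mostly produce Absent calls and
are removed by the filter before a complete matrix is formed.

**What passing tests do and do not show.** The generator reproduces the
correlation structure, noise profile and dynamic range that drive the
relative behaviour of imputation methods on technical replicates, and the
benchmark on it reproduces the field's reference ordering (regression and
regularised global methods best, single-neighbour substitution worst).
It does not model spatial chip geometry, scanner saturation, probe-sequence
biases, or any biological variability — absolute error magnitudes on real
arrays will differ, and the ordering on *biological* (non-replicate)
designs, where columns are far less correlated, is outside what these tests
establish.

## Detection calls

Per probe pair, the discrimination score is `(PM − MM)/(PM + MM)`. Under
the null the probe set's median score equals τ = 0.015; the one-sided
alternative is that it exceeds τ. The p-value comes from the **exact**
Wilcoxon signed-rank null distribution: differences equal to τ are
dropped, tied magnitudes receive midranks, and the null distribution of the
positive-rank sum is built by convolving the n independent two-point
sign distributions over doubled ranks — identical to enumerating all 2ⁿ
sign assignments, in O(n³) time. No normal approximation is used; with
11–20 probe pairs the exact distribution is cheap and reproducible.
Calls use the classic cut-offs: Present if p < 0.04, Marginal if
0.04 ≤ p < 0.06, Absent otherwise.

The test is the one-sample signed-rank test: the tested hypothesis — the
median of a probe set's own scores against a constant τ — is a one-sample
location problem, as in the original detection-call algorithm.

## Summarisation

The spatial zone-background step of the original chip algorithm is omitted
(it needs physical probe coordinates; the synthetic data carries its
background in the noise-floor term). The remaining steps:

* **Ideal mismatch.** Where MM < PM, IM = MM. Otherwise the probe set's
  typical log-ratio SB = biweight(log₂(PM/MM)) substitutes: IM = PM/2^SB
  when SB > 0.03 (the contrast τ), else PM is shrunk by the smoothly
  tapered exponent `0.03 / (1 + (0.03 − SB)/10)`. Always 0 < IM < PM.
* **Biweight summary.** signal = 2^biweight(log₂(max(PM − IM, 2⁻²⁰))),
  with the one-step Tukey biweight (centre = median, spread = 5·MAD + 1e-4,
  quartic weights, no iteration).
* **Scale normalisation.** Each array is multiplied so its 2%-trimmed mean
  equals 500 (or, in baseline-array mode, the first array's trimmed mean).
  Idempotent; scaling all intensities by λ scales all signals by λ.

## Imputation methods

All ten benchmark configurations operate on the raw intensity scale,
preserve observed entries exactly, and return complete matrices.
Degenerate inputs fall back method → row average → global observed mean,
with a log entry.

* **ROW** — row (gene) average of the observed replicates.
* **KNN1/KNN5** — k nearest neighbour genes by root-mean-square difference
  over the columns observed in both rows (per-coordinate normalised so
  different overlap sizes compare fairly; Pearson distance `1 − |r|`
  optional); the missing value is the unweighted mean of the neighbours'
  values at that column. Ties break by row order.
* **SVD** — EM with the leading `q = 2` eigen genes: fill missing with row
  averages, then iterate truncated-SVD reconstruction of the filled matrix,
  replacing missing cells each pass, until the relative total change over
  the masked cells drops below 0.01. The relative-change stop matches the
  classic implementations; an absolute 0.01 is unreachable on raw intensity
  scales and allows the EM to drift. A per-row regression variant
  (`svd_mode="regression"`: observed entries regressed on the eigen genes
  restricted to the observed columns) is provided; with only 3–4 observed
  points per row it has unbounded leverage, so its pseudoinverse truncates
  singular directions below 10% of the leading one and its estimates are
  clipped to the observed dynamic range.
* **LLS1/3/4** — local least squares with k < S. Default mode
  (`"replicates"`): the target column is regressed, without intercept, on
  its k most |Pearson|-correlated replicate columns over all rows observed
  in them — thousands of observations fitting k coefficients — and a
  missing cell is predicted from its row's values on those columns; rows
  lacking some neighbour columns get the best k they have. This is the
  variant that a genes × replicates matrix undergoes in the classic R
  implementation, and the reason k is capped below the replicate count.
  The gene-neighbour mode (`"genes"`) regresses the target row on its k
  most correlated gene rows over the observed columns; because sample
  correlations over ≤ 4 points are nearly uninformative and the k = |O|
  solve interpolates noise with unbounded θ-weighted leverage, its
  pseudoinverse truncates singular directions below 1% of the leading one.
* **LSA** — least squares adaptive: a gene-based estimate (weighted
  univariate regressions on the 10 most correlated complete rows, weights
  `(r²/(1−r²+1e-6))²`) and an array-based estimate (weighted univariate
  regressions of the target column on each other column) are blended with
  a weight p ∈ [0, 1] calibrated on a held-out probe of observed cells
  (5%, seeded): probe cells are binned into quartiles of the
  neighbour-correlation strength r*, and each bin's p minimises the squared
  blend error in closed form. The original publication describes the
  adaptive weighting qualitatively and defers details to external code;
  this binned minimiser is a documented stand-in.
* **BPCA** — variational Bayesian PCA, `y = Wx + μ + ε`, isotropic noise,
  automatic-relevance-determination prior on the columns of W
  (q = S − 1 components; the ARD precisions shrink unneeded ones).
  E-steps are grouped by missing pattern; missing cells take their
  posterior mean; initialisation is the SVD of the row-average-filled
  matrix plus seeded jitter, so runs are deterministic given the seed.
  Stops when the largest imputed-value change drops below 1e-4 of the
  observed value scale.
* **NIPALS** — PCA by alternating score/loading regressions that skip
  missing cells in every inner product (q = 2). Column means computed on
  observed cells alone are biased by the missing rows, so the mean is
  refined in an outer loop: means recomputed from the current filled
  matrix, fit repeated, until imputed values stabilise. Missing cells are
  reconstructed as `mean + Σ t·pᵀ`.

## Error measures and ranking

With `CD` the complete matrix and `ID` the imputed one, scored on the
masked cells only:

* RMSE = √(mean (ŷ−y)²)
* RAE = mean |ŷ−y| / max(|y|, ε), ε = 0.20
* LRMSE = √(mean (log ŷ − log y)²), natural log by default (the base
  rescales all methods equally and never changes ranks)
* RAE-L2 = mean (ŷ−y)²/y (an optional outer square root is config-exposed
  and off by default)

The names of the first and third carry the "root", which fixes the outer
square root lost in some renderings. Estimates below ε are clamped to ε
for the log-scale measure (the same floor RAE uses); a linear imputer can
produce near-zero or negative intensities, and log of an arbitrary tiny
floor would turn a bounded mistake into an unbounded one.

Deletion masks exactly `round(fraction · G · S)` cells (round-half-even),
uniform without replacement, no row protection — fully-missing rows are
the imputers' fallback problem. Within one simulation every method faces
the identical mask; per-simulation seeds are `seed XOR sim`, so any single
simulation can be rerun alone.

Ranking: errors are averaged over simulations per (method, measure, site,
pool); methods are ranked 1 (lowest error) to n per (measure, site, pool)
with midranks for ties (midranks preserve the rank-sum total n(n+1)/2 at
every aggregation level); ranks are averaged over sites within pool, then
over pools — the sequential order matters in principle and is fixed, though
the two orders coincide on balanced designs — and the Average column is the
row-wise mean over the four measures. Failed simulations are excluded from
averages (with a logged count) rather than assigned a worst rank.

## Problem sizes

Unit tests run on matrices of 30–500 genes. The directional benchmark that
reproduces the reference ordering uses one cell of G = 2000 genes ×
5 replicates, 100 Monte-Carlo simulations at 5% deletion with all ten
methods (≈ 1–2 minutes); the full-design pipeline examples use 2 sites ×
2 pools at 40–200 probe sets. These sizes were chosen so the whole suite
and the acceptance script each complete in minutes while keeping every
Monte-Carlo margin comfortable.

## Known limitations

* The generator's distributional choices are stand-ins: the real study's
  data-generating process is unknown, and every parameter is config-exposed
  rather than asserted as fact.
* The probe-level path omits saturation handling and spatial artifacts.
* The gene-neighbour LLS mode and the regression SVD mode are kept for
  completeness but are intrinsically fragile at S = 5; the benchmark
  defaults use the stable variants.
* Rank tables on a single site × pool cell collapse the two-level
  aggregation to a plain mean; the full design exercises both levels.
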