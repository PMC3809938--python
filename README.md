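# imputebench

Benchmark missing-value imputation methods on Affymetrix-style gene
expression data, end to end: synthetic probe-level arrays with the MAQC
factorial structure, MAS 5.0-style detection calls and summarisation,
Monte-Carlo random deletion, ten imputation methods, four error measures,
and rank aggregation into a single method × measure report.

## Who this is for

Missing values in expression matrices — scratches, dust, hybridisation
failures — break downstream clustering, PCA and differential expression,
so they must be imputed. Which imputation method to trust depends on the
data's correlation structure, and the cleanest way to compare methods is a
technical-replicate design: two reference RNAs (UHRR, HBRR) and their
75/25 and 25/75 mixtures, assayed at 6 sites × 5 replicates, give complete
matrices with known values and no biological variability. This package
implements that whole comparison loop as a reusable, seeded library for
anyone studying imputation accuracy or needing a defensible default method
for replicate array data.

## The method in brief

For each site × pool cell:

1. **Detection calls.** Per probe pair, the discrimination score
   `(PM − MM)/(PM + MM)`; per probe set and array, an exact one-sided
   Wilcoxon signed-rank test of H₀: median score = τ (= 0.015) against
   median > τ. Present if p < α₁ (= 0.04), Absent if p ≥ α₂ (= 0.06),
   Marginal in between.
2. **Filter.** Keep probe sets called Present in all 5 replicates → the
   complete matrix `CD = (y_gs)`, G probe sets × 5 arrays.
3. **Summarise.** Ideal mismatch, one-step Tukey biweight of
   `log₂(PM − IM)`, arrays scaled to a common trimmed-mean target.
4. **Benchmark.** Delete a fraction (5% or 10%) of cells uniformly at
   random, impute with each of BPCA, KNN (k = 1, 5), LLS (k = 1, 3, 4),
   LSA, NIPALS, ROW and SVD, and score the imputed matrix `ID = (ŷ_gs)` on
   the masked cells:

   * RMSE = √(mean (ŷ−y)²)
   * RAE  = mean |ŷ−y| / max(|y|, ε), ε = 0.20
   * LRMSE = √(mean (log ŷ − log y)²)
   * RAE-L2 = mean (ŷ−y)²/y

5. **Rank.** Average errors over simulations, rank methods 1..10 per
   measure and cell, average ranks over sites then pools, then over the
   four measures. Smaller average rank = more accurate method.

See `docs/methods.md` for the models, defaults and numerical choices.

## A worked example

```bash
python examples/05_benchmark_and_rank.py
```

generates one correlated 1000-gene × 5-replicate cell, runs 10 simulations
at 5% deletion with all ten methods and prints the rank table:

```
        RMSE  LRMSE   RAE  RAEL2  Average
method
BPCA     1.0    1.0   2.0    1.0     1.25
KNN1     8.0    9.0  10.0    9.0     9.00
KNN5     9.0    5.0   6.0    6.0     6.50
LLS1     5.0    8.0   9.0    8.0     7.50
LLS3     4.0    4.0   3.0    4.0     3.75
LLS4     2.0    2.0   1.0    2.0     1.75
LSA      3.0    6.0   4.0    3.0     4.00
NIPALS  10.0   10.0   8.0   10.0     9.50
ROW      7.0    3.0   5.0    5.0     5.00
SVD      6.0    7.0   7.0    7.0     6.75

best: BPCA   worst: KNN1
```

Each column holds average ranks (1 = lowest error of the ten methods) for
one error measure; the Average column summarises them. Here the
regularised global method (BPCA) and local least squares with k = 4 are the
most accurate, while single-neighbour substitution (KNN1) is among the
worst — replacing a value with one noisy neighbour keeps all of that
neighbour's noise, whereas averaging and regression methods pool
information across replicates.

The other examples walk the remaining stages: probe-level generation
(`01`), detection calls and percent-present (`02`), summarisation (`03`),
single-matrix imputation (`04`) and the full multi-site study (`06`).

A thin CLI mirrors the stages:

```bash
impute-bench generate --seed 1 --out-prefix data
impute-bench detect --probes data_probes.tsv --samples data_samples.tsv --out calls.tsv
impute-bench all --seed 1 --out study_out
```

## Layout

```
src/imputebench/    library (synthetic data, detection, preprocessing,
                    imputation, evaluation, ranking, pipeline, CLI)
examples/           one narrative script per capability
tests/              pytest suite, including acceptance checks
scripts/            acceptance script
docs/methods.md     models, parameters, design choices, limitations
```
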