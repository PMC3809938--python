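"""End-to-end study orchestration.

``run_study`` executes generate -> detect -> filter -> summarise ->
benchmark -> rank for every site x pool cell of the factorial design, writes
every intermediate as TSV under an output directory, and records a JSON
manifest (config echo, seeds, versions, per-stage row counts) from which the
whole run is re-derivable.  All per-cell seeds are keyed by the cell
identity, not execution order, so results are independent of processing
order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .detection import DetectionParams, detect, filter_complete, percent_present
from .errors import ConfigError, ImputeBenchError
from .evaluation import EvalConfig, run_benchmark
from .imputation import MethodConfig, canonical_method_configs
from .preprocess import PreprocessParams, scale_normalize, summarize
from .ranking import aggregate_ranks, average_over_sims, best_worst
from .synthetic import GeneratorConfig, generate_dataset

__all__ = ["StudyConfig", "run_study"]

logger = logging.getLogger(__name__)


def _cell_seed(master_seed: int, site: str, pool: str, tag: str) -> int:
    """Deterministic sub-seed keyed by cell identity (order-independent)."""
    h = zlib.crc32(f"{tag}:{site}:{pool}".encode())
    return int((master_seed ^ h) % (2**31))


@dataclass
class StudyConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    eval: EvalConfig = field(default_factory=EvalConfig)
    methods: list[MethodConfig] = field(default_factory=canonical_method_configs)
    deletion_fractions: list[float] = field(default_factory=lambda: [0.05, 0.10])
    output_dir: str | Path = "study_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        self.generator.validate()
        self.detection.validate()
        self.preprocess.validate()
        self.eval.validate()
        labels = [m.name for m in self.methods]
        if len(set(labels)) != len(labels):
            raise ConfigError("method labels must be unique")
        for f in self.deletion_fractions:
            if not 0 < f < 1:
                raise ConfigError("deletion_fractions must lie in (0, 1)")

    def to_manifest_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, Path):
                return str(obj)
            return obj
        return {
            "generator": enc(self.generator),
            "detection": enc(self.detection),
            "preprocess": enc(self.preprocess),
            "eval": enc(self.eval),
            "methods": [enc(m) for m in self.methods],
            "deletion_fractions": list(self.deletion_fractions),
        }


def run_study(cfg: StudyConfig) -> dict:
    """Run the full study; returns a dict of in-memory artifacts.

    Writes, under ``cfg.output_dir``: the probe-level table and sample
    sheet, detection calls and percent-present tables, one complete
    expression matrix and retained-id list per site x pool cell, the
    long-format benchmark results per deletion fraction, one rank table per
    deletion fraction, and ``manifest.json``.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage=generate: probe-level dataset (G=%d)", cfg.generator.n_probe_sets)
    table = generate_dataset(cfg.generator)
    io.write_probe_table(table.probes, out / "probe_table.tsv")
    io.write_sample_sheet(table.samples, out / "samples.tsv")

    logger.info("stage=detect: %d probe sets x %d arrays",
                cfg.generator.n_probe_sets, len(table.samples))
    calls = detect(table, cfg.detection)
    io.write_calls(calls, out / "calls.tsv")
    per_array, per_cell = percent_present(calls, table.samples)
    per_array.to_csv(out / "percent_present.tsv", sep="\t", index=False, float_format="%.10g")
    per_cell.to_csv(out / "percent_present_by_cell.tsv", sep="\t", index=False, float_format="%.10g")

    cells = table.samples[["site", "pool"]].drop_duplicates().itertuples(index=False)
    matrices: dict[tuple[str, str], pd.DataFrame] = {}
    counts: dict[str, int] = {}
    for site, pool in cells:
        tag = f"{site}_{pool}"
        retained = filter_complete(calls, table.samples, site, pool)
        io.write_id_list(retained, out / f"retained_{tag}.txt")
        counts[tag] = len(retained)
        if not retained:
            raise ImputeBenchError(f"stage=filter cell={tag}: no probe set present in all replicates")
        logger.info("stage=filter cell=%s: retained %d probe sets", tag, len(retained))
        cell_samples = list(table.samples.loc[
            (table.samples["site"] == site) & (table.samples["pool"] == pool), "sample_id"])
        matrix = summarize(table, retained, cfg.preprocess, sample_ids=cell_samples)
        matrix = scale_normalize(matrix, cfg.preprocess)
        io.write_expression_matrix(matrix, out / f"expression_{tag}.tsv")
        matrices[(site, pool)] = matrix

    all_reports: dict[float, pd.DataFrame] = {}
    rank_tables: dict[float, pd.DataFrame] = {}
    for frac in cfg.deletion_fractions:
        frames = []
        for (site, pool), matrix in matrices.items():
            ev = EvalConfig(deletion_fraction=frac, n_simulations=cfg.eval.n_simulations,
                            epsilon=cfg.eval.epsilon, log_base=cfg.eval.log_base,
                            rae_l2_root=cfg.eval.rae_l2_root,
                            seed=_cell_seed(cfg.eval.seed, site, pool, f"bench{frac}"))
            logger.info("stage=benchmark cell=%s_%s fraction=%.2f sims=%d",
                        site, pool, frac, ev.n_simulations)
            frames.append(run_benchmark(matrix, cfg.methods, ev, site=site, pool=pool))
        reports = pd.concat(frames, ignore_index=True)
        tagf = f"{int(round(frac * 100))}pct"
        reports.to_csv(out / f"benchmark_{tagf}.tsv", sep="\t", index=False, float_format="%.10g")
        all_reports[frac] = reports

        rt = aggregate_ranks(average_over_sims(reports))
        rt.to_csv(out / f"ranks_{tagf}.tsv", sep="\t", float_format="%.10g")
        rank_tables[frac] = rt
        logger.info("stage=rank fraction=%.2f best=%s worst=%s", frac,
                    best_worst(rt)["Average"]["best"], best_worst(rt)["Average"]["worst"])

    manifest = {
        "config": cfg.to_manifest_dict(),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "retained_counts": counts,
        "n_cells": len(matrices),
        "n_reports": {str(f): len(r) for f, r in all_reports.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "table": table,
        "calls": calls,
        "percent_present": per_array,
        "percent_present_by_cell": per_cell,
        "matrices": matrices,
        "reports": all_reports,
        "rank_tables": rank_tables,
        "manifest": manifest,
    }
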