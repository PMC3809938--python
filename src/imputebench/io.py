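"""Plain-text (TSV) readers and writers for the package's tabular formats.

All intermediate artifacts are tab-separated text so that a study run can be
inspected, diffed and round-tripped without binary tooling:

* probe-level table: ``probe_set_id  probe_pair_index  sample_id  pm  mm``
* sample sheet:      ``sample_id  site  pool  replicate``
* expression matrix: first column ``probe_set_id``, one column per sample;
  missing cells are encoded as ``NA``
* detection calls:   ``probe_set_id  sample_id  p_value  call``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["probe_set_id", "probe_pair_index", "sample_id", "pm", "mm"]
SAMPLE_COLUMNS = ["sample_id", "site", "pool", "replicate"]
CALL_COLUMNS = ["probe_set_id", "sample_id", "p_value", "call"]

# fixed float formatting so identical data always serialises to identical bytes
_FLOAT_FMT = "%.10g"


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_set_id": str, "sample_id": str})
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe-level table missing columns: {sorted(missing)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str, "pool": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix; NaN cells become ``NA``."""
    out = matrix.copy()
    out.index.name = "probe_set_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return df


def write_calls(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe_set_id": str, "sample_id": str})


def write_id_list(ids, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(i) for i in ids) + "\n")


def read_id_list(path: str | Path) -> list[str]:
    return [line for line in Path(path).read_text().splitlines() if line]


def write_mask(mask: np.ndarray, row_ids, col_ids, path: str | Path) -> None:
    df = pd.DataFrame(mask.astype(int), index=row_ids, columns=col_ids)
    df.index.name = "probe_set_id"
    df.to_csv(path, sep="\t")


def read_mask(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)
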