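"""Delimited-text I/O for matrices, linkages, assignments and grid tables.

All tables are TSV with fixed column orders; floats are printed with six
significant digits.  FCGE matrices have a header row of DC labels and the
gene IDs in the first column; comma-delimited input is accepted and
auto-detected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cocluster import CoClusterGrid
from .hclust import ClusterAssignment, Linkage

__all__ = [
    "read_fcge_matrix",
    "write_matrix",
    "write_linkage",
    "write_assignment",
    "read_assignment",
    "write_grid_table",
    "read_grid_table",
    "write_scc_report",
    "load_config_file",
]

FLOAT_FMT = "%.6g"
GRID_COLUMNS = ["GC", "DCC", "aLFCGE", "n_cells", "rank", "significance"]


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_fcge_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate an FCGE matrix from TSV/CSV.

    Rejects duplicate labels and non-numeric or missing cells, naming the
    offending coordinates.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs {dupes}")
    if raw.columns.has_duplicates:
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate DC labels {dupes}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() | raw.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        cell = raw.iloc[r, c]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r} (value {cell!r})"
        )
    values.index.name = raw.index.name or "gene"
    return values


def write_matrix(f: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = f.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    return path


def write_linkage(t: Linkage, path: str | Path) -> Path:
    path = Path(path)
    t.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def write_assignment(a: ClusterAssignment, path: str | Path) -> Path:
    path = Path(path)
    a.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_assignment(path: str | Path, axis: str = "gene") -> ClusterAssignment:
    df = pd.read_csv(path, sep="\t")
    codes = df["cluster"].to_numpy(dtype=int)
    return ClusterAssignment(df["item"].astype(str).tolist(), codes, int(codes.max()), axis)


def write_grid_table(grid: CoClusterGrid, path: str | Path) -> Path:
    """Co-cluster table: GC, DCC, aLFCGE, n_cells, rank, significance."""
    path = Path(path)
    t = grid.table.rename(
        columns={"gene_cluster": "GC", "dc_cluster": "DCC", "mean": "aLFCGE"}
    )[GRID_COLUMNS]
    t.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_grid_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_scc_report(report: pd.DataFrame, path: str | Path) -> Path:
    """One row per plotted statistic: value, CL, LCL, UCL, call."""
    path = Path(path)
    report.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline config file into a flat dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
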