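"""Co-cluster grid construction, ranking and matrix reordering.

Every (gene cluster, DC cluster) pair defines one co-cluster block; its
statistic is the arithmetic mean of the (transformed) fold-change values it
contains -- the aLFCGE.  Blocks are then relabelled so that the largest
block means run down the principal diagonal: repeatedly take the largest
mean among blocks whose gene cluster and DC cluster are both still
unlabelled and give both axes the next index.  The relabelling is a pure
permutation of cluster indices; the multiset of block means is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .hclust import ClusterAssignment

__all__ = ["CoClusterGrid", "ReorderedMatrix", "build_grid", "rank_and_relabel", "reorder_matrix"]

UNSET = "unset"


@dataclass
class CoClusterGrid:
    """All g x d co-cluster blocks plus the axis relabelling maps.

    ``table`` columns: gene_cluster, dc_cluster, mean (aLFCGE), n_cells,
    rank (0 until ranked), significance ({'up','down','insignificant'} once
    classified).  ``gene_map``/``dc_map`` map original cluster ids to the
    diagonalised ids (identity until :func:`rank_and_relabel`).
    """

    table: pd.DataFrame
    gene_assign: ClusterAssignment
    dc_assign: ClusterAssignment
    gene_map: dict[int, int]
    dc_map: dict[int, int]
    ranked: bool = False

    @property
    def n_blocks(self) -> int:
        return len(self.table)

    def mean_matrix(self) -> np.ndarray:
        """Block means as a (gene clusters x DC clusters) array."""
        g, d = self.gene_assign.k, self.dc_assign.k
        m = np.empty((g, d))
        for row in self.table.itertuples():
            m[row.gene_cluster - 1, row.dc_cluster - 1] = row.mean
        return m

    def block(self, gc: int, dcc: int) -> pd.Series:
        t = self.table
        return t[(t.gene_cluster == gc) & (t.dc_cluster == dcc)].iloc[0]


def build_grid(
    x: pd.DataFrame, gc: ClusterAssignment, dcc: ClusterAssignment
) -> CoClusterGrid:
    """Per-block means of ``x`` over the two cluster assignments (unranked)."""
    missing_rows = [l for l in x.index if l not in set(gc.labels)]
    missing_cols = [l for l in x.columns if l not in set(dcc.labels)]
    if missing_rows or missing_cols or len(gc.labels) != len(x.index) or len(dcc.labels) != len(x.columns):
        raise ValueError(
            "assignments do not cover the matrix labels exactly; "
            f"unassigned rows: {missing_rows[:5]}, unassigned columns: {missing_cols[:5]}"
        )
    rcodes = np.array([gc.codes[gc.labels.index(l)] for l in x.index])
    ccodes = np.array([dcc.codes[dcc.labels.index(l)] for l in x.columns])
    vals = x.to_numpy(dtype=float)
    g, d = gc.k, dcc.k
    sums = np.zeros((g, d))
    counts = np.zeros((g, d), dtype=int)
    np.add.at(sums, (rcodes[:, None] - 1, ccodes[None, :] - 1), vals)
    np.add.at(counts, (rcodes[:, None] - 1, ccodes[None, :] - 1), 1)
    rows = [
        {
            "gene_cluster": i + 1,
            "dc_cluster": j + 1,
            "mean": sums[i, j] / counts[i, j],
            "n_cells": counts[i, j],
            "rank": 0,
            "significance": UNSET,
        }
        for i in range(g)
        for j in range(d)
    ]
    return CoClusterGrid(
        pd.DataFrame(rows),
        gc,
        dcc,
        {i + 1: i + 1 for i in range(g)},
        {j + 1: j + 1 for j in range(d)},
        ranked=False,
    )


def rank_and_relabel(grid: CoClusterGrid) -> CoClusterGrid:
    """Greedy diagonalisation: top block means onto the descending diagonal.

    Iteratively pick the largest-mean block whose gene and DC clusters are
    both unlabelled and assign both the next diagonal index; ties go to the
    smallest original (gene id, dc id).  Once one axis is exhausted the
    remaining clusters on the other axis follow in descending order of
    their maximal block mean.  Idempotent: re-ranking a ranked grid only
    permutes indices that are already in diagonal order.
    """
    g, d = grid.gene_assign.k, grid.dc_assign.k
    m = grid.mean_matrix()
    gene_map: dict[int, int] = {}
    dc_map: dict[int, int] = {}
    for t in range(1, min(g, d) + 1):
        best = None
        for i in range(1, g + 1):
            if i in gene_map:
                continue
            for j in range(1, d + 1):
                if j in dc_map:
                    continue
                key = (-m[i - 1, j - 1], i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        gene_map[i] = t
        dc_map[j] = t
    # leftover clusters on the longer axis: by descending max block mean
    for axis_map, size, other in ((gene_map, g, 0), (dc_map, d, 1)):
        left = [c for c in range(1, size + 1) if c not in axis_map]
        maxmean = {
            c: (m[c - 1, :].max() if other == 0 else m[:, c - 1].max()) for c in left
        }
        for c in sorted(left, key=lambda c: (-maxmean[c], c)):
            axis_map[c] = len(axis_map) + 1

    table = grid.table.copy()
    table["gene_cluster"] = table["gene_cluster"].map(gene_map)
    table["dc_cluster"] = table["dc_cluster"].map(dc_map)
    order = table.sort_values(
        ["mean", "gene_cluster", "dc_cluster"], ascending=[False, True, True]
    ).index
    table.loc[order, "rank"] = np.arange(1, len(table) + 1)
    table = table.sort_values("rank").reset_index(drop=True)

    ga = grid.gene_assign
    da = grid.dc_assign
    new_ga = replace(ga, codes=np.array([gene_map[c] for c in ga.codes]))
    new_da = replace(da, codes=np.array([dc_map[c] for c in da.codes]))
    compose_g = {orig: gene_map[cur] for orig, cur in grid.gene_map.items()}
    compose_d = {orig: dc_map[cur] for orig, cur in grid.dc_map.items()}
    return CoClusterGrid(table, new_ga, new_da, compose_g, compose_d, ranked=True)


@dataclass
class ReorderedMatrix:
    """A matrix permuted into contiguous relabelled blocks."""

    matrix: pd.DataFrame
    row_boundaries: list[int]  # cumulative row counts after each gene cluster
    col_boundaries: list[int]
    row_perm: np.ndarray  # positions into the source row order
    col_perm: np.ndarray


def reorder_matrix(x: pd.DataFrame, grid: CoClusterGrid) -> ReorderedMatrix:
    """Permute rows/columns of ``x`` into contiguous blocks of a ranked grid."""
    if not grid.ranked:
        raise ValueError("reorder_matrix requires a ranked grid")
    ga, da = grid.gene_assign, grid.dc_assign
    rcodes = np.array([ga.codes[ga.labels.index(l)] for l in x.index])
    ccodes = np.array([da.codes[da.labels.index(l)] for l in x.columns])
    row_perm = np.argsort(rcodes, kind="stable")
    col_perm = np.argsort(ccodes, kind="stable")
    out = x.iloc[row_perm, :].iloc[:, col_perm]
    row_b = np.cumsum(np.bincount(rcodes)[1:]).tolist()
    col_b = np.cumsum(np.bincount(ccodes)[1:]).tolist()
    return ReorderedMatrix(out, row_b, col_b, row_perm, col_perm)
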