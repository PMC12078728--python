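"""Gene-chemical regulatory networks built from a classified co-cluster grid.

Two bipartite views: the *cluster-level* network has one node per gene
cluster and per DC cluster and one edge per co-cluster block (complete
bipartite), weighted by the block's aLFCGE and typed by its significance
call; the *member-level* network expands each (optionally only
significant) block into complete bipartite gene-DC edges inheriting the
block's weight and class.  Edge colour semantics are left to downstream
renderers -- the categorical ``cls`` attribute carries the call.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .cocluster import CoClusterGrid
from .hclust import ClusterAssignment

__all__ = [
    "build_cluster_network",
    "build_member_network",
    "export_network",
    "read_edge_list",
]

EDGE_COLUMNS = ["source", "target", "weight", "cls", "level"]


def _require_classified(grid: CoClusterGrid) -> None:
    if (grid.table["significance"] == "unset").any():
        raise ValueError("grid has no significance calls; run classify_coclusters first")


def build_cluster_network(grid: CoClusterGrid) -> nx.Graph:
    """Complete bipartite GC-DCC network, one edge per co-cluster block."""
    _require_classified(grid)
    g = nx.Graph(level="cluster")
    for row in grid.table.itertuples():
        u, v = f"GC{row.gene_cluster}", f"DCC{row.dc_cluster}"
        g.add_node(u, kind="gene_cluster")
        g.add_node(v, kind="dc_cluster")
        g.add_edge(u, v, weight=float(row.mean), cls=row.significance, level="cluster")
    return g


def build_member_network(
    grid: CoClusterGrid,
    gc: ClusterAssignment | None = None,
    dcc: ClusterAssignment | None = None,
    significant_only: bool = False,
) -> nx.Graph:
    """Gene-DC bipartite network expanded through (significant) blocks.

    Assignments default to the (relabelled) ones stored on the grid.
    """
    _require_classified(grid)
    gc = gc or grid.gene_assign
    dcc = dcc or grid.dc_assign
    g = nx.Graph(level="member")
    for row in grid.table.itertuples():
        if significant_only and row.significance == "insignificant":
            continue
        genes = gc.members(row.gene_cluster)
        dcs = dcc.members(row.dc_cluster)
        for gene in genes:
            g.add_node(gene, kind="gene")
        for dc in dcs:
            g.add_node(dc, kind="dc")
        for gene in genes:
            for dc in dcs:
                g.add_edge(
                    gene, dc, weight=float(row.mean), cls=row.significance, level="member"
                )
    return g


def export_network(n: nx.Graph, path: str | Path, fmt: str = "tsv") -> Path:
    """Write a network as an edge-list TSV or GraphML file."""
    path = Path(path)
    if fmt == "tsv":
        rows = [
            {"source": u, "target": v, "weight": d["weight"], "cls": d["cls"], "level": d["level"]}
            for u, v, d in n.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif fmt == "graphml":
        nx.write_graphml(n, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; choose 'tsv' or 'graphml'")
    return path


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read back an exported edge-list TSV."""
    return pd.read_csv(path, sep="\t")
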