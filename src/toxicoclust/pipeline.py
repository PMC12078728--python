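"""End-to-end co-clustering pipeline and its results bundle.

``run_pipeline`` chains the whole method: (simulate or load) an FCGE
matrix -> logistic transform (robust mode only) -> two hierarchical
clusterings -> co-cluster grid, diagonal ranking -> control-chart
significance calls -> reordered matrix and networks.  Everything is
written into the output directory atomically (staged in a temp dir, then
renamed) so a crashed run never leaves a half-written bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .cocluster import CoClusterGrid, ReorderedMatrix, build_grid, rank_and_relabel, reorder_matrix
from .control_chart import ControlLimits, classify_coclusters
from .hclust import ClusterAssignment, Linkage, agglomerate, cut_tree, pairwise_distance
from .network import build_cluster_network, build_member_network, export_network
from .preprocess import logistic_transform, validate_fcge
from .simulate import ContaminationConfig, SimulationConfig, contaminate_icm, contaminate_thcm, generate_fcge

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("toxicoclust")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through JSON/YAML."""

    input: str | None = None  # FCGE matrix path; None => simulate
    simulate: bool = False
    mode: str = "robust"  # 'robust' (transform first) or 'classical'
    metric: str = "euclidean"
    linkage: str = "ward.d2"
    minkowski_p: float = 2.0
    k_genes: int = 4
    k_dcs: int = 3
    estimator: str = "xbar_overall"
    k_sigma: float = 3.0
    contamination_model: str | None = None  # 'thcm' | 'icm'
    contamination_rate: float = 0.0
    noise_variance: float = 0.35
    outdir: str = "toxicoclust_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("robust", "classical"):
            raise ValueError(f"mode must be 'robust' or 'classical', got {self.mode!r}")
        if self.input is None and not self.simulate:
            raise ValueError("either give an input matrix or set simulate=True")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    fcge: pd.DataFrame
    working: pd.DataFrame  # transformed in robust mode, raw otherwise
    gene_linkage: Linkage
    dc_linkage: Linkage
    gene_assign: ClusterAssignment
    dc_assign: ClusterAssignment
    grid: CoClusterGrid
    limits: ControlLimits
    reordered: ReorderedMatrix
    outdir: Path | None = None


def _versions() -> dict:
    import networkx
    import scipy

    from . import __version__

    return {
        "toxicoclust": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }


def _obtain_matrix(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.input is not None:
        f = tio.read_fcge_matrix(cfg.input)
    else:
        sim = SimulationConfig(noise_variance=cfg.noise_variance, seed=cfg.seed)
        f, _ = generate_fcge(sim)
        if cfg.contamination_model and cfg.contamination_rate > 0:
            ccfg = ContaminationConfig(
                model=cfg.contamination_model, rate=cfg.contamination_rate,
                seed=cfg.seed + 1,
            )
            contam = contaminate_thcm if cfg.contamination_model == "thcm" else contaminate_icm
            f, _ = contam(f, ccfg)
    return validate_fcge(f)


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    if cfg.k_genes < 1 or cfg.k_dcs < 1:
        raise ValueError("cluster counts must be >= 1")
    f = _obtain_matrix(cfg)
    if cfg.k_genes > f.shape[0] or cfg.k_dcs > f.shape[1]:
        raise ValueError(
            f"requested k_genes={cfg.k_genes}, k_dcs={cfg.k_dcs} exceed matrix "
            f"shape {f.shape}"
        )
    log.info("FCGE matrix: %d genes x %d DCs", *f.shape)

    x = logistic_transform(f) if cfg.mode == "robust" else f
    gd = pairwise_distance(x, "gene", cfg.metric, cfg.minkowski_p)
    dd = pairwise_distance(x, "dc", cfg.metric, cfg.minkowski_p)
    gl = agglomerate(gd, cfg.linkage)
    dl = agglomerate(dd, cfg.linkage)
    ga = cut_tree(gl, cfg.k_genes, "gene")
    da = cut_tree(dl, cfg.k_dcs, "dc")

    grid = rank_and_relabel(build_grid(x, ga, da))
    grid, limits = classify_coclusters(
        grid, x=x, estimator=cfg.estimator, k_sigma=cfg.k_sigma
    )
    reordered = reorder_matrix(x, grid)
    result = PipelineResult(
        f, x, gl, dl, grid.gene_assign, grid.dc_assign, grid, limits, reordered
    )
    counts = grid.table["significance"].value_counts().to_dict()
    log.info("co-cluster calls: %s", counts)
    if write:
        result.outdir = _write_bundle(cfg, result)
    return result


def _write_bundle(cfg: PipelineConfig, r: PipelineResult) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".staging-", dir=outdir))
    try:
        tio.write_matrix(r.fcge, tmp / "fcge.tsv")
        tio.write_matrix(r.working, tmp / "transformed.tsv")
        tio.write_linkage(r.gene_linkage, tmp / "linkage_genes.tsv")
        tio.write_linkage(r.dc_linkage, tmp / "linkage_dcs.tsv")
        tio.write_assignment(r.gene_assign, tmp / "clusters_genes.tsv")
        tio.write_assignment(r.dc_assign, tmp / "clusters_dcs.tsv")
        tio.write_grid_table(r.grid, tmp / "coclusters.tsv")

        lim = r.limits
        report = r.grid.table.rename(
            columns={"gene_cluster": "GC", "dc_cluster": "DCC", "mean": "value"}
        )[["GC", "DCC", "value", "significance"]].copy()
        report.insert(3, "CL", lim.cl)
        report.insert(4, "LCL", lim.lcl)
        report.insert(5, "UCL", lim.ucl)
        report = report.rename(columns={"significance": "call"})
        tio.write_scc_report(report, tmp / "scc_report.tsv")

        tio.write_matrix(r.reordered.matrix, tmp / "reordered.tsv")
        (tmp / "block_boundaries.json").write_text(
            json.dumps(
                {
                    "row_boundaries": r.reordered.row_boundaries,
                    "col_boundaries": r.reordered.col_boundaries,
                },
                indent=2,
            )
        )
        export_network(build_cluster_network(r.grid), tmp / "network_clusters.tsv")
        export_network(build_cluster_network(r.grid), tmp / "network_clusters.graphml", "graphml")
        export_network(build_member_network(r.grid), tmp / "network_members.tsv")
        (tmp / "manifest.json").write_text(
            json.dumps({"config": cfg.to_dict(), "versions": _versions()}, indent=2)
        )
        for name in os.listdir(tmp):
            os.replace(tmp / name, outdir / name)
    finally:
        for leftover in tmp.glob("*"):
            leftover.unlink()
        tmp.rmdir()
    log.info("results written to %s", outdir)
    return outdir
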