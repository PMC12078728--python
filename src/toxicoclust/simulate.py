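"""Block-structured FCGE simulator with casewise/cellwise contamination.

The default design emulates a pathway-level toxicogenomic experiment at a
single time point: 50 genes in four true clusters (sizes 10/10/10/20) by
36 doses-of-chemicals in three true clusters, built from 12 chemicals at
Low/Middle/High dose.  Block means (gene cluster x DC cluster):

    GC1  [+3,  0,  0]       DCC1 = chemicals 1-5  at Middle/High
    GC2  [-3, +3,  0]       DCC2 = chemicals 6-10 at Middle/High
    GC3  [ 0, -3,  0]       DCC3 = every Low dose, plus chemicals 11-12
    GC4  [ 0,  0,  0]              at Middle/High

i.i.d. Gaussian noise with variance 0.35 is added to every cell.  The ±3
blocks are the planted up-/down-regulatory co-clusters; DCC3 and GC4 carry
no signal.

Contamination replaces clean entries with draws from N(±10, 1) (sign
random per cell), far outside the ±3 signal range:

* THCM (Tukey-Huber, casewise): each gene row is independently selected
  with probability ``rate`` and replaced wholesale;
* ICM (independent, cellwise): each cell is independently replaced with
  probability ``rate``.  A cell rate of 0.025 at C = 36 makes the chance
  a row carries at least one outlier 1 - 0.975**36 = 0.598, the casewise-
  equivalent endpoint of the contamination sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .hclust import ClusterAssignment

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ContaminationConfig",
    "default_dc_design",
    "generate_fcge",
    "generate_replicate_stack",
    "contaminate_thcm",
    "contaminate_icm",
    "icm_casewise_equivalent",
]

DEFAULT_BLOCK_MEANS = np.array(
    [[3.0, 0.0, 0.0], [-3.0, 3.0, 0.0], [0.0, -3.0, 0.0], [0.0, 0.0, 0.0]]
)


def default_dc_design() -> tuple[list[str], np.ndarray]:
    """Labels and true cluster codes for the 36 default DC columns.

    Columns run chemical-major (C1_Low, C1_Middle, C1_High, C2_Low, ...).
    """
    labels, codes = [], []
    for chem in range(1, 13):
        for dose in ("Low", "Middle", "High"):
            labels.append(f"C{chem}_{dose}")
            if dose == "Low" or chem >= 11:
                codes.append(3)
            elif chem <= 5:
                codes.append(1)
            else:
                codes.append(2)
    return labels, np.array(codes)


@dataclass
class SimulationConfig:
    gene_cluster_sizes: tuple[int, ...] = (10, 10, 10, 20)
    block_means: np.ndarray = field(default_factory=lambda: DEFAULT_BLOCK_MEANS.copy())
    noise_variance: float = 0.35
    dc_labels: list[str] | None = None  # default: the 12-chemical x 3-dose design
    dc_codes: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.block_means = np.asarray(self.block_means, dtype=float)
        if self.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")
        if self.dc_labels is None:
            self.dc_labels, self.dc_codes = default_dc_design()
        self.dc_codes = np.asarray(self.dc_codes, dtype=int)
        g, d = self.block_means.shape
        if len(self.gene_cluster_sizes) != g:
            raise ValueError(
                f"{len(self.gene_cluster_sizes)} gene cluster sizes but "
                f"block-mean matrix has {g} rows"
            )
        if self.dc_codes.max() != d or len(self.dc_labels) != len(self.dc_codes):
            raise ValueError(
                f"DC design uses clusters 1..{self.dc_codes.max()} over "
                f"{len(self.dc_labels)} labels but block-mean matrix has {d} columns"
            )

    @property
    def n_genes(self) -> int:
        return int(sum(self.gene_cluster_sizes))

    @property
    def n_dcs(self) -> int:
        return len(self.dc_labels)

    def gene_codes(self) -> np.ndarray:
        return np.repeat(
            np.arange(1, len(self.gene_cluster_sizes) + 1), self.gene_cluster_sizes
        )


@dataclass
class GroundTruth:
    gene_clusters: ClusterAssignment
    dc_clusters: ClusterAssignment
    regulation: pd.DataFrame  # gene cluster x DC cluster in {'up','down','none'}
    mask: pd.DataFrame  # contamination mask; all-False straight out of the generator


@dataclass
class ContaminationConfig:
    model: Literal["thcm", "icm"] = "thcm"
    rate: float = 0.0
    outlier_mean: float = 10.0  # magnitude; sign is random per replacement
    outlier_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("contamination rate must be in [0, 1]")
        if self.model not in ("thcm", "icm"):
            raise ValueError(f"unknown contamination model {self.model!r}")


def _signal_matrix(cfg: SimulationConfig) -> np.ndarray:
    gcodes = cfg.gene_codes()
    return cfg.block_means[gcodes[:, None] - 1, cfg.dc_codes[None, :] - 1]


def generate_fcge(
    cfg: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one FCGE matrix: block mean + N(0, noise_variance) per cell."""
    cfg = cfg or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    signal = _signal_matrix(cfg)
    noise = rng.normal(0.0, np.sqrt(cfg.noise_variance), size=signal.shape)
    genes = [f"G{i + 1}" for i in range(cfg.n_genes)]
    f = pd.DataFrame(signal + noise, index=genes, columns=list(cfg.dc_labels))

    gcodes = cfg.gene_codes()
    reg = np.where(cfg.block_means > 0, "up", np.where(cfg.block_means < 0, "down", "none"))
    truth = GroundTruth(
        gene_clusters=ClusterAssignment(genes, gcodes, int(gcodes.max()), "gene"),
        dc_clusters=ClusterAssignment(
            list(cfg.dc_labels), cfg.dc_codes, int(cfg.dc_codes.max()), "dc"
        ),
        regulation=pd.DataFrame(
            reg,
            index=[f"GC{i + 1}" for i in range(cfg.block_means.shape[0])],
            columns=[f"DCC{j + 1}" for j in range(cfg.block_means.shape[1])],
        ),
        mask=pd.DataFrame(False, index=genes, columns=list(cfg.dc_labels)),
    )
    return f, truth


def generate_replicate_stack(
    cfg: SimulationConfig | None = None,
    m: int = 3,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Replicate-level draws FC_pqr, shape (N, C, m), for cell-level charts.

    Each replicate is block mean + N(0, noise_variance); the replicate mean
    therefore has variance ``noise_variance / m`` (the mean-level generator
    :func:`generate_fcge` is the one matching the analysed matrix).
    """
    cfg = cfg or SimulationConfig()
    if m < 1:
        raise ValueError("need m >= 1 replicates")
    if rng is None or not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    signal = _signal_matrix(cfg)
    return signal[:, :, None] + rng.normal(
        0.0, np.sqrt(cfg.noise_variance), size=signal.shape + (m,)
    )


def _outliers(rng: np.random.Generator, n: int, c: ContaminationConfig) -> np.ndarray:
    signs = rng.choice([-1.0, 1.0], size=n)
    return signs * rng.normal(c.outlier_mean, c.outlier_sd, size=n)


def contaminate_thcm(
    f: pd.DataFrame, c: ContaminationConfig, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Casewise contamination: whole gene rows replaced with prob ``rate``."""
    if rng is None or not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(c.seed if rng is None else rng)
    vals = f.to_numpy(dtype=float).copy()
    rows = rng.random(vals.shape[0]) < c.rate
    mask = np.zeros(vals.shape, dtype=bool)
    mask[rows, :] = True
    vals[mask] = _outliers(rng, int(mask.sum()), c)
    return (
        pd.DataFrame(vals, index=f.index, columns=f.columns),
        pd.DataFrame(mask, index=f.index, columns=f.columns),
    )


def contaminate_icm(
    f: pd.DataFrame, c: ContaminationConfig, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cellwise contamination: each cell independently replaced with prob ``rate``."""
    if rng is None or not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(c.seed if rng is None else rng)
    vals = f.to_numpy(dtype=float).copy()
    mask = rng.random(vals.shape) < c.rate
    vals[mask] = _outliers(rng, int(mask.sum()), c)
    return (
        pd.DataFrame(vals, index=f.index, columns=f.columns),
        pd.DataFrame(mask, index=f.index, columns=f.columns),
    )


def icm_casewise_equivalent(cell_rate: float, n_cols: int) -> float:
    """Probability a row carries >= 1 cellwise outlier: 1 - (1 - rate)^C."""
    return 1.0 - (1.0 - cell_rate) ** n_cols
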