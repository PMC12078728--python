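"""Shewhart-style control limits for regulation calls.

Two charts are used at two stages of the pipeline:

* an *individuals* chart on the fold-change scale classifies single
  gene-DC cells as up-/down-/un-regulated (``cell >= UCL`` is up,
  ``cell <= LCL`` is down, boundaries inclusive);
* an *x-bar* chart on the logistic-transformed scale classifies co-cluster
  blocks: the plotted statistics are the block means (aLFCGE) with the
  blocks as subgroups, and a block is significantly upregulatory when its
  mean is strictly above UCL, downregulatory when strictly below LCL.

Three sigma estimators are available for the x-bar chart:

``xbar_overall`` (default)
    sigma is the overall standard deviation of all cell values and the
    limits are ``CL +/- k * sigma / sqrt(nbar)`` with ``nbar`` the mean
    subgroup size.  Because genuinely regulated blocks sit far from the
    centre with very small within-block spread on the transformed scale,
    the overall sd gives conservative limits whose familywise false-alarm
    rate on in-control blocks is far below the per-block 3-sigma rate.
``xbar_pooled``
    classic pooled within-subgroup sd in place of the overall sd.
``individuals``
    ``CL +/- k * sd(all values)`` -- no subgroup structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cocluster import CoClusterGrid

__all__ = [
    "ControlLimits",
    "compute_limits",
    "classify_cells",
    "cocluster_subgroups",
    "classify_coclusters",
    "ESTIMATORS",
]

ESTIMATORS = ("individuals", "xbar_pooled", "xbar_overall")


@dataclass
class ControlLimits:
    cl: float
    lcl: float
    ucl: float
    estimator: str
    k_sigma: float
    sigma_hat: float
    nbar: float  # effective subgroup size (1 for individuals)

    def __post_init__(self) -> None:
        if not self.lcl <= self.cl <= self.ucl:
            raise ValueError("control limits must satisfy LCL <= CL <= UCL")


def _as_groups(values, subgroups) -> list[np.ndarray]:
    if subgroups is None:
        raise ValueError("x-bar estimators need subgroups")
    if values is None:
        groups = [np.asarray(g, dtype=float).ravel() for g in subgroups]
    else:
        values = np.asarray(values, dtype=float).ravel()
        labels = np.asarray(subgroups).ravel()
        if len(labels) != len(values):
            raise ValueError("subgroup labels must align with values")
        groups = [values[labels == u] for u in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 subgroups with >= 2 members each")
    return groups


def compute_limits(
    values: Sequence[float] | np.ndarray | None = None,
    subgroups: Iterable | None = None,
    estimator: str = "individuals",
    k_sigma: float = 3.0,
) -> ControlLimits:
    """Center line and control limits.

    ``values`` is the flat sample for the individuals chart.  For the x-bar
    charts pass either ``subgroups`` as a list of arrays, or ``values``
    plus an aligned array of subgroup labels.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if k_sigma < 0:
        raise ValueError("k_sigma must be >= 0")

    if estimator == "individuals":
        vals = np.asarray(values, dtype=float).ravel()
        if len(vals) < 2:
            raise ValueError("need >= 2 values")
        cl = float(vals.mean())
        sigma = float(vals.std(ddof=1))
        half = k_sigma * sigma
        return ControlLimits(cl, cl - half, cl + half, estimator, k_sigma, sigma, 1.0)

    groups = _as_groups(values, subgroups)
    allv = np.concatenate(groups)
    cl = float(allv.mean())
    nbar = float(np.mean([len(g) for g in groups]))
    if estimator == "xbar_pooled":
        num = sum((len(g) - 1) * g.var(ddof=1) for g in groups)
        den = sum(len(g) - 1 for g in groups)
        sigma = float(np.sqrt(num / den))
    else:  # xbar_overall
        sigma = float(allv.std(ddof=1))
    half = k_sigma * sigma / np.sqrt(nbar)
    return ControlLimits(cl, cl - half, cl + half, estimator, k_sigma, sigma, nbar)


def classify_cells(f: pd.DataFrame, lim: ControlLimits) -> pd.DataFrame:
    """Per-cell regulation call: ``>= UCL`` up, ``<= LCL`` down, else unregulated."""
    vals = f.to_numpy(dtype=float)
    out = np.full(vals.shape, "unregulated", dtype=object)
    out[vals >= lim.ucl] = "up"
    out[vals <= lim.lcl] = "down"
    return pd.DataFrame(out, index=f.index, columns=f.columns)


def cocluster_subgroups(x: pd.DataFrame, grid: CoClusterGrid) -> list[np.ndarray]:
    """The cell values of each co-cluster block, as chart subgroups."""
    ga, da = grid.gene_assign, grid.dc_assign
    rcodes = np.array([ga.codes[ga.labels.index(l)] for l in x.index])
    ccodes = np.array([da.codes[da.labels.index(l)] for l in x.columns])
    vals = x.to_numpy(dtype=float)
    groups = []
    for row in grid.table.itertuples():
        block = vals[np.ix_(rcodes == row.gene_cluster, ccodes == row.dc_cluster)]
        groups.append(block.ravel())
    return groups


def classify_coclusters(
    grid: CoClusterGrid,
    x: pd.DataFrame | None = None,
    lim: ControlLimits | None = None,
    estimator: str = "xbar_overall",
    k_sigma: float = 3.0,
) -> tuple[CoClusterGrid, ControlLimits]:
    """Fill the significance column of a grid from an x-bar chart.

    Either pass precomputed ``lim`` or the matrix ``x`` the grid was built
    from (limits are then computed with the blocks as subgroups).  Calls
    are strict: ``mean > UCL`` -> up, ``mean < LCL`` -> down.
    """
    if lim is None:
        if x is None:
            raise ValueError("need either precomputed limits or the source matrix")
        lim = compute_limits(
            subgroups=cocluster_subgroups(x, grid), estimator=estimator, k_sigma=k_sigma
        )
    table = grid.table.copy()
    means = table["mean"].to_numpy()
    sig = np.full(len(table), "insignificant", dtype=object)
    sig[means > lim.ucl] = "up"
    sig[means < lim.lcl] = "down"
    table["significance"] = sig
    return replace(grid, table=table), lim
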