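"""Robustness diagnostics: clustering error rate and sensitivity curves.

The error rate (ER) between a predicted and a true partition is the
percentage of items left unmatched after the clusters are paired one-to-one
to maximise total overlap (optimal assignment on the contingency table).
That matching makes ER invariant to any relabelling of either partition;
when the two partitions use different numbers of clusters, members of
unmatched clusters all count as errors.

The sensitivity curve probes how one contaminated observation moves the
1-norm profile distance T between two genes:

    SC_n(y*) = n * [ T(y_1, ..., y_{n-1}, y*) - T(y_1, ..., y_{n-1}) ]

In robust mode every value (including the contaminant) passes through the
logistic transform first, so the appended term |L(y*) - ref| is bounded by
max(ref, 1 - ref) and SC_n stays finite however extreme y* becomes; in
classical mode the raw |y* - ref| grows without bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .hclust import ClusterAssignment, agglomerate, cut_tree, pairwise_distance
from .preprocess import logistic_transform
from .simulate import (
    ContaminationConfig,
    SimulationConfig,
    contaminate_icm,
    contaminate_thcm,
    generate_fcge,
)

__all__ = [
    "ErrorRateReport",
    "SensitivityCurve",
    "error_rate",
    "profile_distance",
    "sensitivity_curve",
    "run_comparison_sweep",
    "DEFAULT_COMBOS",
    "DEFAULT_THCM_RATES",
    "DEFAULT_ICM_RATES",
]

DEFAULT_COMBOS = tuple(
    (metric, link)
    for metric in ("euclidean", "manhattan", "minkowski")
    for link in ("ward.d", "ward.d2")
)
DEFAULT_THCM_RATES = (0.0, 0.1, 0.2, 0.3, 0.4)
DEFAULT_ICM_RATES = (0.0, 0.00625, 0.0125, 0.01875, 0.025)


@dataclass
class ErrorRateReport:
    er: float  # percent misclustered, 0..100
    contingency: pd.DataFrame  # predicted x true counts
    matching: dict[int, int]  # predicted cluster -> matched true cluster
    axis: str

    def __repr__(self) -> str:
        return f"ErrorRateReport(er={self.er:.3f}%, axis={self.axis!r})"


def error_rate(
    predicted: ClusterAssignment, truth: ClusterAssignment
) -> ErrorRateReport:
    """Percent of items misclustered under optimal one-to-one label matching."""
    if set(predicted.labels) != set(truth.labels):
        raise ValueError("predicted and true assignments cover different item sets")
    t_of = dict(zip(truth.labels, truth.codes))
    tcodes = np.array([t_of[l] for l in predicted.labels])
    table = np.zeros((predicted.k, truth.k), dtype=int)
    np.add.at(table, (predicted.codes - 1, tcodes - 1), 1)
    rows, cols = linear_sum_assignment(table, maximize=True)
    matched = int(table[rows, cols].sum())
    n = len(predicted.labels)
    er = 100.0 * (1.0 - matched / n)
    return ErrorRateReport(
        er,
        pd.DataFrame(
            table,
            index=[f"pred{i + 1}" for i in range(predicted.k)],
            columns=[f"true{j + 1}" for j in range(truth.k)],
        ),
        {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)},
        predicted.axis,
    )


def profile_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """1-norm distance between two equal-length profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"profiles must be 1-D and equal length; got {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


@dataclass
class SensitivityCurve:
    grid: np.ndarray  # contaminant values y*
    sc: np.ndarray  # SC_n(y*)
    mode: str
    n: int
    reference: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"y_star": self.grid, "sc": self.sc})


def sensitivity_curve(
    gene_i: Sequence[float],
    gene_k: Sequence[float],
    grid: Sequence[float] | None = None,
    mode: str = "robust",
    reference: float | None = None,
) -> SensitivityCurve:
    """Finite-sample sensitivity curve of the profile distance.

    ``gene_i``/``gene_k`` are the clean fold-change profiles of length
    n - 1; the contaminant y* is appended as gene_i's n-th coordinate and
    compared against ``reference`` on gene_k's side (default: the mean of
    gene_k's working-scale profile).  Robust mode works on the
    logistic-transformed scale, classical mode on raw values.
    """
    if mode not in ("robust", "classical"):
        raise ValueError(f"mode must be 'robust' or 'classical', got {mode!r}")
    a = np.asarray(gene_i, dtype=float)
    b = np.asarray(gene_k, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("profiles must be non-empty")
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    ys = np.linspace(-10.0, 10.0, 201) if grid is None else np.asarray(grid, dtype=float)
    if mode == "robust":
        a, b = logistic_transform(a), logistic_transform(b)
        ystar = logistic_transform(ys)
    else:
        ystar = ys
    ref = float(b.mean()) if reference is None else float(reference)
    n = a.size + 1
    # T with the appended coordinate minus T without it: only the new term
    sc = n * np.abs(ystar - ref)
    return SensitivityCurve(ys, sc, mode, n, ref)


def _cluster_genes(
    f: pd.DataFrame, mode: str, metric: str, linkage: str, k: int, p: float = 2.0
) -> ClusterAssignment:
    x = logistic_transform(f) if mode == "robust" else f
    d = pairwise_distance(x, axis="gene", metric=metric, p=p)
    return cut_tree(agglomerate(d, linkage), k, axis="gene")


def run_comparison_sweep(
    sim: SimulationConfig | None = None,
    models: Iterable[ContaminationConfig] | None = None,
    combos: Iterable[tuple[str, str]] = DEFAULT_COMBOS,
    modes: Iterable[str] = ("robust", "classical"),
    n_seeds: int = 30,
    base_seed: int = 0,
    minkowski_p: float = 2.0,
) -> pd.DataFrame:
    """Gene-clustering ER across contamination rates, distance-linkage
    combinations and robust/classical modes, averaged over seeds.

    Each (seed, model) pair shares one generated + contaminated matrix
    across all combos and modes, so the comparison is paired.  Output has
    one row per (model, rate, metric, linkage, mode) with the mean and sd
    of ER over seeds.
    """
    sim = sim or SimulationConfig()
    if models is None:
        models = [
            ContaminationConfig(model="thcm", rate=r) for r in DEFAULT_THCM_RATES
        ]
    models = list(models)
    combos = list(combos)
    modes = list(modes)
    k = len(sim.gene_cluster_sizes)

    ss = np.random.SeedSequence(base_seed)
    seeds = ss.spawn(n_seeds)
    records: dict[tuple, list[float]] = {
        (m.model, m.rate, metric, link, mode): []
        for m in models
        for metric, link in combos
        for mode in modes
    }
    for seed in seeds:
        rng = np.random.default_rng(seed)
        clean, truth = generate_fcge(sim, rng)
        for m in models:
            if m.rate == 0:
                f = clean
            elif m.model == "thcm":
                f, _ = contaminate_thcm(clean, m, rng)
            else:
                f, _ = contaminate_icm(clean, m, rng)
            for metric, link in combos:
                for mode in modes:
                    pred = _cluster_genes(f, mode, metric, link, k, minkowski_p)
                    rep = error_rate(pred, truth.gene_clusters)
                    records[(m.model, m.rate, metric, link, mode)].append(rep.er)

    rows = [
        {
            "model": key[0],
            "rate": key[1],
            "metric": key[2],
            "linkage": key[3],
            "mode": key[4],
            "er_mean": float(np.mean(ers)),
            "er_sd": float(np.std(ers, ddof=1)) if len(ers) > 1 else 0.0,
            "n_seeds": len(ers),
        }
        for key, ers in records.items()
    ]
    return pd.DataFrame(rows)
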