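"""Two-way agglomerative hierarchical clustering with R-hclust Ward variants.

Genes and DCs are clustered separately (rows and columns of the matrix).
Distances are ordinary Lp profile distances via :func:`scipy.spatial.distance.pdist`.
The agglomeration itself is a Lance-Williams implementation written here
because the two Ward variants must reproduce R's ``hclust`` semantics:

* ``ward.d``  -- the Lance-Williams Ward recurrence applied to the
  dissimilarities exactly as given (R "ward.D");
* ``ward.d2`` -- the same recurrence on squared dissimilarities, with
  reported merge heights being square roots (R "ward.D2"; equals scipy's
  ``ward`` on Euclidean input).

Ties in the minimal merge cost (within 1e-12) are broken toward the
lexicographically smallest (left id, right id) pair, which makes the merge
order fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "Linkage",
    "ClusterAssignment",
    "pairwise_distance",
    "agglomerate",
    "cut_tree",
    "suggest_k",
    "METRICS",
    "LINKAGES",
]

METRICS = ("euclidean", "manhattan", "minkowski")
LINKAGES = ("ward.d", "ward.d2", "single", "complete", "average")

_TIE_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Condensed pairwise dissimilarities over ``n`` labelled items."""

    condensed: np.ndarray
    labels: list[str]
    metric: str
    p: float = 2.0

    @property
    def n(self) -> int:
        return len(self.labels)

    def square(self) -> np.ndarray:
        return squareform(self.condensed)


@dataclass
class Linkage:
    """Merge history: rows (left id, right id, height, merged size).

    Ids follow the scipy convention: originals are ``0..n-1``, the cluster
    created by merge ``i`` has id ``n + i``.
    """

    merges: np.ndarray  # (n-1, 4) float
    labels: list[str]
    method: str
    metric: str = ""

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        ).astype({"left": int, "right": int, "size": int})


@dataclass
class ClusterAssignment:
    """A partition of labelled items into clusters ``1..k``.

    Cluster indices are assigned by order of first member appearance in the
    input item order.
    """

    labels: list[str]
    codes: np.ndarray  # int, values in 1..k
    k: int
    axis: Literal["gene", "dc"] = "gene"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if len(self.codes) != len(self.labels):
            raise ValueError("codes and labels differ in length")
        present = np.unique(self.codes)
        if len(present) != self.k or present.min() < 1 or present.max() > self.k:
            raise ValueError(
                f"expected exactly {self.k} non-empty clusters numbered 1..{self.k}; "
                f"found {present.tolist()}"
            )

    def members(self, cluster: int) -> list[str]:
        return [l for l, c in zip(self.labels, self.codes) if c == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item": self.labels, "cluster": self.codes})


def pairwise_distance(
    m: pd.DataFrame,
    axis: Literal["gene", "dc"] = "gene",
    metric: str = "euclidean",
    p: float = 2.0,
) -> DistanceMatrix:
    """Lp distances between row (gene) or column (DC) profiles."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if p < 1:
        raise ValueError(f"Minkowski order must be >= 1, got {p}")
    if axis == "gene":
        data, labels = m.to_numpy(dtype=float), list(m.index)
    elif axis == "dc":
        data, labels = m.to_numpy(dtype=float).T, list(m.columns)
    else:
        raise ValueError(f"axis must be 'gene' or 'dc', got {axis!r}")
    if len(labels) < 2:
        raise ValueError("need at least 2 items to compute distances")
    if metric == "euclidean":
        cond = pdist(data, metric="euclidean")
    elif metric == "manhattan":
        cond = pdist(data, metric="cityblock")
    else:
        cond = pdist(data, metric="minkowski", p=p)
    return DistanceMatrix(cond, labels, metric, p)


def _lw_update(
    method: str,
    d_ac: np.ndarray,
    d_bc: np.ndarray,
    d_ab: float,
    n_a: int,
    n_b: int,
    n_c: np.ndarray,
) -> np.ndarray:
    if method in ("ward.d", "ward.d2"):
        tot = n_a + n_b + n_c
        return ((n_a + n_c) * d_ac + (n_b + n_c) * d_bc - n_c * d_ab) / tot
    if method == "single":
        return np.minimum(d_ac, d_bc)
    if method == "complete":
        return np.maximum(d_ac, d_bc)
    if method == "average":
        return (n_a * d_ac + n_b * d_bc) / (n_a + n_b)
    raise ValueError(f"unknown linkage {method!r}; choose from {LINKAGES}")


def agglomerate(d: DistanceMatrix, method: str = "ward.d2") -> Linkage:
    """Lance-Williams agglomeration of a distance matrix.

    Returns the full merge history; heights are on the dissimilarity scale
    (square roots of the working values for ``ward.d2``).
    """
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; choose from {LINKAGES}")
    n = d.n
    if n < 2:
        raise ValueError("need at least 2 items to agglomerate")

    # working dissimilarities: squared for ward.d2
    big = 2 * n - 1
    work = np.full((big, big), np.inf)
    sq = d.square()
    if method == "ward.d2":
        sq = sq**2
    work[:n, :n] = sq
    np.fill_diagonal(work, np.inf)

    sizes = np.zeros(big, dtype=int)
    sizes[:n] = 1
    active = np.zeros(big, dtype=bool)
    active[:n] = True
    merges = np.empty((n - 1, 4))

    for step in range(n - 1):
        idx = np.flatnonzero(active)
        sub = work[np.ix_(idx, idx)]
        m0 = sub.min()
        # tie-break: lexicographically smallest (left, right) among near-minimal
        cand = np.argwhere(sub <= m0 + _TIE_TOL)
        pairs = sorted(
            (min(idx[a], idx[b]), max(idx[a], idx[b])) for a, b in cand if a != b
        )
        i, j = pairs[0]
        d_ab = work[i, j]
        height = np.sqrt(d_ab) if method == "ward.d2" else d_ab

        new = n + step
        others = idx[(idx != i) & (idx != j)]
        if len(others):
            work[new, others] = _lw_update(
                method, work[i, others], work[j, others], d_ab,
                sizes[i], sizes[j], sizes[others],
            )
            work[others, new] = work[new, others]
        sizes[new] = sizes[i] + sizes[j]
        active[[i, j]] = False
        active[new] = True
        merges[step] = (i, j, height, sizes[new])

    return Linkage(merges, list(d.labels), method, d.metric)


def cut_tree(
    t: Linkage, k: int, axis: Literal["gene", "dc"] = "gene"
) -> ClusterAssignment:
    """Partition into ``k`` clusters by undoing the last ``k - 1`` merges."""
    n = t.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    parent = np.arange(2 * n - 1)
    for step in range(n - k):
        left, right = int(t.merges[step, 0]), int(t.merges[step, 1])
        parent[left] = parent[right] = n + step

    def root(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    roots = np.array([root(i) for i in range(n)])
    codes = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen) + 1
        codes[i] = seen[r]
    return ClusterAssignment(list(t.labels), codes, k, axis)


def suggest_k(t: Linkage, k_max: int = 10) -> tuple[int, pd.DataFrame]:
    """Advisory cluster count from the largest gap between merge heights.

    For each candidate ``k`` the gap is the height of the merge that would
    reduce ``k`` clusters to ``k - 1``, minus the height of the last merge
    performed to reach ``k`` clusters.  Ties go to the smaller ``k``.  This
    mimics choosing the cut level "by eye" on a dendrogram; the pipeline
    itself always takes an explicit ``k``.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    n = t.n
    h = t.heights
    ks = np.arange(2, min(k_max, n - 1) + 1)
    gaps = np.array([h[n - k] - h[n - k - 1] for k in ks])
    best = int(ks[np.argmax(gaps)])  # argmax returns first (smallest k) on ties
    return best, pd.DataFrame({"k": ks, "gap": gaps})
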