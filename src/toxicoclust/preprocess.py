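"""Fold-change construction and the bounded logistic transform.

The analysis operates on a fold-change gene expression (FCGE) matrix:
rows are genes, columns are doses-of-chemicals (DCs, one treated
condition = chemical x dose level x time point), and each entry is the
mean log2 ratio of treated over control expression across replicates.

Robustness of the downstream co-clustering comes entirely from the
logistic transform applied here: ``L(f) = 1 / (1 + exp(-f))`` maps any
fold change into the open interval (0, 1), so a wild outlier can move a
transformed value by at most ~0.5 instead of arbitrarily far.  L(0) is
exactly 0.5, the "unregulated" midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTensor",
    "compute_fold_change",
    "average_replicates",
    "logistic_transform",
    "validate_fcge",
]


@dataclass
class ExpressionTensor:
    """Raw expression intensities indexed (chemical, dose, time, replicate).

    ``values`` has shape (P, Q, T, m) and must be strictly positive
    (a log2 is taken).  Treated and control tensors must share labels.
    """

    values: np.ndarray
    chemicals: Sequence[str]
    doses: Sequence[str]
    times: Sequence[str] = field(default_factory=lambda: ["t1"])
    replicates: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(
                f"expression tensor must be 4-D (chemical, dose, time, replicate); "
                f"got shape {self.values.shape}"
            )
        p, q, t, m = self.values.shape
        if self.replicates is None:
            self.replicates = [f"r{i + 1}" for i in range(m)]
        for name, labels, size in (
            ("chemicals", self.chemicals, p),
            ("doses", self.doses, q),
            ("times", self.times, t),
            ("replicates", self.replicates, m),
        ):
            if len(labels) != size:
                raise ValueError(
                    f"{name} labels ({len(labels)}) do not match axis size {size}"
                )

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape

    def _labels(self) -> tuple:
        return (
            tuple(self.chemicals),
            tuple(self.doses),
            tuple(self.times),
            tuple(self.replicates),
        )


def _check_positive(t: ExpressionTensor, role: str) -> None:
    if not np.all(np.isfinite(t.values)):
        idx = np.argwhere(~np.isfinite(t.values))[0]
        raise ValueError(f"{role} tensor has non-finite value at index {tuple(idx)}")
    if np.any(t.values <= 0):
        idx = np.argwhere(t.values <= 0)[0]
        p, q, tt, r = idx
        raise ValueError(
            f"{role} tensor has nonpositive value at "
            f"(chemical={t.chemicals[p]}, dose={t.doses[q]}, "
            f"time={t.times[tt]}, replicate={t.replicates[r]}); "
            "expression intensities must be > 0 for log2"
        )


def compute_fold_change(
    treated: ExpressionTensor, control: ExpressionTensor
) -> np.ndarray:
    """Per-replicate log2 fold change, ``log2(treated) - log2(control)``.

    Returns an array of shape (P, Q, T, m) matching the input tensors.
    """
    if treated.shape != control.shape:
        raise ValueError(
            f"treated shape {treated.shape} != control shape {control.shape}"
        )
    if treated._labels() != control._labels():
        raise ValueError("treated and control tensors must share axis labels")
    _check_positive(treated, "treated")
    _check_positive(control, "control")
    return np.log2(treated.values) - np.log2(control.values)


def average_replicates(
    fc: np.ndarray,
    gene_ids: Sequence[str] | None = None,
    chemicals: Sequence[str] | None = None,
    doses: Sequence[str] | None = None,
    times: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Average a per-replicate fold-change stack into an FCGE matrix.

    Two layouts are accepted:

    * shape (N, C, m): genes x conditions x replicates -> (N, C) matrix;
    * shape (P, Q, T, m): a single gene's condition tensor -> (1, C) with
      the (p, q, t) axes flattened chemical-major, then dose, then time.

    Column labels are ``<chemical>_<dose>_<time>`` (or positional when no
    labels are supplied) so the flattening order is unambiguous.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim == 4:
        p, q, t, m = fc.shape
        if m == 0:
            raise ValueError("replicate axis is empty (m = 0)")
        mean = fc.mean(axis=3).reshape(1, p * q * t)
        chemicals = chemicals or [f"C{i + 1}" for i in range(p)]
        doses = doses or [f"D{i + 1}" for i in range(q)]
        times = times or [f"T{i + 1}" for i in range(t)]
        cols = [
            f"{c}_{d}_{tt}" for c in chemicals for d in doses for tt in times
        ]
        index = list(gene_ids) if gene_ids is not None else ["G1"]
        return pd.DataFrame(mean, index=index, columns=cols)
    if fc.ndim == 3:
        n, c, m = fc.shape
        if m == 0:
            raise ValueError("replicate axis is empty (m = 0)")
        index = list(gene_ids) if gene_ids is not None else [f"G{i + 1}" for i in range(n)]
        cols = [f"DC{j + 1}" for j in range(c)]
        return pd.DataFrame(fc.mean(axis=2), index=index, columns=cols)
    raise ValueError(
        f"expected a 3-D (gene, condition, replicate) or 4-D "
        f"(chemical, dose, time, replicate) stack; got ndim={fc.ndim}"
    )


def validate_fcge(f: pd.DataFrame) -> pd.DataFrame:
    """Check FCGE matrix invariants: finite values, unique labels."""
    if f.index.has_duplicates:
        dupes = f.index[f.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dupes}")
    if f.columns.has_duplicates:
        dupes = f.columns[f.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate DC labels: {dupes}")
    vals = f.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        r, c = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite FCGE value at gene={f.index[r]!r}, DC={f.columns[c]!r}"
        )
    return f


def logistic_transform(f: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Map fold changes into (0, 1) via ``x = 1 / (1 + exp(-f))``.

    Computed in the two-branch numerically stable form so that inputs like
    -1e6 give a tiny positive value instead of overflowing ``exp``.
    Labels are preserved when a DataFrame is given.
    """
    values = f.to_numpy(dtype=float) if isinstance(f, pd.DataFrame) else np.asarray(f, dtype=float)
    if np.any(np.isnan(values)):
        raise ValueError("logistic_transform: input contains NaN")
    out = np.empty_like(values, dtype=float)
    pos = values >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-values[pos]))
    ev = np.exp(values[~pos])
    out[~pos] = ev / (1.0 + ev)
    if isinstance(f, pd.DataFrame):
        return pd.DataFrame(out, index=f.index, columns=f.columns)
    return out
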