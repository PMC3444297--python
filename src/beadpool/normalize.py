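"""Log transformation, quantile normalization, and array-level QC statistics.

With one array per condition there are no biological replicates to diagnose,
but technical bias between arrays is still visible in the intensity
distributions.  The QC contract here is numeric: MA statistics for every
array pair and correlation-based array distances; rendering the classic
plots from those numbers is left to the caller.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import SCALE_LINEAR, SCALE_LOG2, BeadSummary, NormalizedMatrix
from .errors import ValidationError


def log2_transform(bs: BeadSummary, offset: float = 1.0) -> NormalizedMatrix:
    """log2-transform the mean signals: ``value = log2(signal + offset)``.

    The offset (default 1 intensity unit) guards zero signals.  Applying the
    transform to data already on the log2 scale is an error rather than a
    silent double transform.
    """
    if bs.scale == SCALE_LOG2:
        raise ValidationError("matrix is already on the log2 scale")
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    x = bs.mean_signal.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("negative signal; cannot log-transform")
    if offset == 0 and (x == 0).any():
        raise ValidationError("zero signal with zero offset")
    values = pd.DataFrame(
        np.log2(x + offset), index=bs.mean_signal.index, columns=bs.mean_signal.columns
    )
    return NormalizedMatrix(values, provenance=[f"log2(x+{offset:g})"])


def quantile_normalize(m: NormalizedMatrix) -> NormalizedMatrix:
    """Force every column onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns; each column's
    values are replaced by the reference values at their ranks.  Tied values
    within a column receive the mean of the reference values over the tied
    rank positions, so the operation remains well defined (and deterministic)
    under ties.  After the operation every column holds the identical value
    multiset (exactly so for tie-free input).
    """
    x = m.values.to_numpy(dtype=float)
    n, k = x.shape
    if k < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return NormalizedMatrix(m.values.copy(), m.provenance + ["quantile(noop)"])
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.take_along_axis(x, order, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(k):
        col_sorted = x[order[:, j], j]
        ref = reference.copy()
        # average reference values over runs of tied input values
        start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    ref[start:i] = ref[start:i].mean()
                start = i
        out[order[:, j], j] = ref
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return NormalizedMatrix(values, m.provenance + ["quantile"])


def ma_statistics(
    m: NormalizedMatrix, pair: tuple[str, str]
) -> pd.DataFrame:
    """Per-probe M (log ratio) and A (mean log2 intensity) for an array pair.

    M = col1 - col2, A = (col1 + col2) / 2.
    """
    g1, g2 = pair
    for g in (g1, g2):
        if g not in m.values.columns:
            raise ValidationError(f"unknown group label {g!r}")
    c1 = m.values[g1]
    c2 = m.values[g2]
    return pd.DataFrame({"M": c1 - c2, "A": (c1 + c2) / 2.0})


def array_cluster_distances(m: NormalizedMatrix) -> pd.DataFrame:
    """Group x group distance matrix, 1 - Pearson correlation of columns.

    Zero diagonal, symmetric, values in [0, 2].  A zero-variance column has
    no defined correlation; its off-diagonal distances are reported as NaN.
    """
    if m.values.shape[0] < 3:
        raise ValidationError("need at least 3 probes for array distances")
    x = m.values.to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    dist = 1.0 - corr
    degenerate = sd == 0
    dist[degenerate, :] = np.nan
    dist[:, degenerate] = np.nan
    np.fill_diagonal(dist, 0.0)
    labels = m.values.columns
    return pd.DataFrame(dist, index=labels, columns=labels)
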