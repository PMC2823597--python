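"""Between-array normalization primitives.

All operations are pure matrix transforms on a pandas DataFrame
(rows = genes or probes, columns = arrays) and preserve the row/column
labels.  Scale bookkeeping (linear vs log2) is the caller's job; the
pipeline driver in :mod:`mirnaprep.summarize` handles it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import MirnaPrepError

__all__ = [
    "shift_positive",
    "scale_to_percentile75",
    "quantile_normalize",
    "log2_transform",
]


def _check_finite(df: pd.DataFrame, op: str) -> None:
    if not np.isfinite(df.to_numpy()).all():
        raise MirnaPrepError(f"{op}: non-finite entries in input")


def shift_positive(m: pd.DataFrame) -> pd.DataFrame:
    """Make a linear-scale matrix strictly positive ahead of the log.

    If the global minimum is <= 0, add |min| + 2 to *every* entry (one
    constant for the whole matrix, so between-array relations are shifted,
    not distorted); otherwise return the input unchanged.  After a shift the
    minimum is exactly 2.
    """
    _check_finite(m, "shift_positive")
    lo = float(m.to_numpy().min())
    if lo > 0:
        return m
    return m + (abs(lo) + 2.0)


def scale_to_percentile75(m: pd.DataFrame) -> pd.DataFrame:
    """Divide each array (column) by its own 75th percentile.

    Quantiles interpolate linearly between order statistics (position
    1 + (n-1)q of the sorted column), so afterwards every column's 75th
    percentile equals 1 exactly.
    """
    _check_finite(m, "scale_to_percentile75")
    p75 = m.quantile(0.75, interpolation="linear")
    if (p75 <= 0).any():
        bad = p75.index[p75 <= 0].tolist()
        raise MirnaPrepError(
            f"non-positive 75th percentile for arrays {bad}; "
            "apply shift_positive first"
        )
    return m / p75


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force all columns to share one intensity distribution.

    The reference distribution is the vector of row-wise means of the
    column-sorted matrix; each value is replaced by the reference value at
    its within-column rank.  Ties within a column receive the mean of the
    reference values spanning their tied ranks, so the result is
    deterministic and rank order is preserved.
    """
    _check_finite(m, "quantile_normalize")
    if m.shape[1] < 2:
        raise MirnaPrepError("quantile normalization needs at least 2 arrays")
    x = m.to_numpy(dtype=float)
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        col_sorted = x[order, j]
        vals = ref.copy()
        # average the reference over runs of tied input values
        start = 0
        for end in range(1, n + 1):
            if end == n or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    vals[start:end] = vals[start:end].mean()
                start = end
        out[order, j] = vals
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def log2_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Element-wise log2; every entry must be strictly positive."""
    _check_finite(m, "log2_transform")
    x = m.to_numpy()
    if (x <= 0).any():
        i, j = np.argwhere(x <= 0)[0]
        raise MirnaPrepError(
            f"log2_transform: non-positive entry at row {m.index[i]!r}, "
            f"column {m.columns[j]!r}"
        )
    return pd.DataFrame(np.log2(x), index=m.index, columns=m.columns)
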