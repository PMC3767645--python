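"""Quantile normalization of per-window densities across samples.

The reference distribution is the row-wise mean of the column-sorted matrix
(the standard microarray-style construction).  Each value is replaced by the
reference value at its within-column rank; ties within a column receive the
mean of the reference values over the tied rank span.  Tie handling matters
here because window counts are small integers with massive ties at zero.
"""

from __future__ import annotations

import warnings

import numpy as np


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a 2-D array.

    Parameters
    ----------
    values
        Array of shape (n_rows, n_samples), all finite.

    Returns
    -------
    Array of the same shape in which every column has the identical
    multiset of values (the reference distribution) and within-column rank
    order is weakly preserved.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("expected a 2-D matrix with at least one row")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in input matrix")
    n, k = values.shape
    if k < 2:
        warnings.warn("single-column matrix: quantile normalization is a no-op", stacklevel=2)
        return values.copy()

    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(k):
        col_sorted = sorted_vals[:, j]
        # group boundaries of tied runs in the sorted column
        starts = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        sums = np.add.reduceat(reference, starts)
        lengths = np.diff(np.r_[starts, n])
        group_means = sums / lengths
        per_rank = np.repeat(group_means, lengths)
        out[order[:, j], j] = per_rank
    return out


def cpm_normalize(counts: np.ndarray, library_sizes) -> np.ndarray:
    """Counts-per-million scaling, offered as a sensitivity-analysis alternative."""
    lib = np.asarray(library_sizes, dtype=float)
    if (lib < 1).any():
        raise ValueError("library sizes must be >= 1")
    return np.asarray(counts, dtype=float) / lib[None, :] * 1e6
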