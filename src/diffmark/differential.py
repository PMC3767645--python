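"""Per-window differential testing and FDR-controlled selection.

With one library per condition and no replicates, the per-window test is the
exact conditional binomial: conditioned on the window total n = a + b, the
condition-B count is Binomial(n, pi0) under the null, with
pi0 = N_B / (N_A + N_B) given library sizes N_A, N_B.  Two-sided p-values
are formed by tail doubling (observed point included in each tail, doubled
probability capped at 1).  The test uses RAW counts; the reported effect
size ``delta`` is the difference of quantile-normalized densities (B - A),
so effects are comparable across samples while the test remains exact.

Windows with a + b == 0 carry no information and are excluded both from
testing and from the Benjamini-Hochberg multiplicity count m.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .windows import CountMatrix

DIRECTION_B = "higher_in_B"
DIRECTION_A = "higher_in_A"
DIRECTION_NONE = "none"


def window_pvalue(count_A: int, count_B: int, libsize_A: int, libsize_B: int) -> float:
    """Exact conditional binomial two-sided p-value for one window.

    Under the null, count_B ~ Binomial(count_A + count_B, pi0) with
    pi0 = libsize_B / (libsize_A + libsize_B);
    p = min(1, 2 * min(lower tail, upper tail)), point included in each tail.
    """
    if count_A < 0 or count_B < 0:
        raise ValueError("counts must be non-negative")
    if libsize_A < 1 or libsize_B < 1:
        raise ValueError("library sizes must be >= 1")
    n = count_A + count_B
    if n == 0:
        raise ValueError("count_A + count_B == 0: window is untestable")
    pi0 = libsize_B / (libsize_A + libsize_B)
    lower = stats.binom.cdf(count_B, n, pi0)
    upper = stats.binom.sf(count_B - 1, n, pi0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def window_pvalues(count_A: np.ndarray, count_B: np.ndarray, libsize_A: int, libsize_B: int) -> np.ndarray:
    """Vectorized :func:`window_pvalue` over arrays of window counts."""
    a = np.asarray(count_A, dtype=np.int64)
    b = np.asarray(count_B, dtype=np.int64)
    n = a + b
    if (n == 0).any():
        raise ValueError("untestable windows (a + b == 0) must be excluded first")
    pi0 = libsize_B / (libsize_A + libsize_B)
    lower = stats.binom.cdf(b, n, pi0)
    upper = stats.binom.sf(b - 1, n, pi0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j) on the sorted p-values, mapped back
    to input order; tied p-values share a q-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_table(matrix: CountMatrix, normalized: np.ndarray, sample_A: str = "A", sample_B: str = "B") -> pd.DataFrame:
    """Build the per-window differential table.

    Parameters
    ----------
    matrix
        Two-sample count matrix on a window grid.
    normalized
        Quantile-normalized density matrix aligned with ``matrix`` rows.

    Returns
    -------
    DataFrame over TESTED windows (count_A + count_B >= 1) with columns
    chrom, start, end, count_A, count_B, delta, p, q, direction.
    """
    ia = matrix.sample_labels.index(sample_A)
    ib = matrix.sample_labels.index(sample_B)
    a = matrix.counts[:, ia]
    b = matrix.counts[:, ib]
    tested = (a + b) >= 1
    df = matrix.grid.to_frame().loc[tested].reset_index(drop=True)
    df["count_A"] = a[tested]
    df["count_B"] = b[tested]
    delta = normalized[tested, ib] - normalized[tested, ia]
    df["delta"] = delta
    df["p"] = window_pvalues(a[tested], b[tested], matrix.library_sizes[ia], matrix.library_sizes[ib])
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["direction"] = np.select(
        [delta > 0, delta < 0], [DIRECTION_B, DIRECTION_A], default=DIRECTION_NONE
    )
    return df


def select_windows(results: pd.DataFrame, q_threshold: float = 0.001) -> pd.DataFrame:
    """Windows with q < q_threshold; zero-delta windows are never selected."""
    if not 0 <= q_threshold <= 1:
        raise ValueError("q_threshold must lie in [0, 1]")
    keep = (results["q"] < q_threshold) & (results["direction"] != DIRECTION_NONE)
    return results.loc[keep].reset_index(drop=True)
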