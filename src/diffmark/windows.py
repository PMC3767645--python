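"""Genome tiling windows and per-window tag counting.

The genome is tiled into fixed-width windows (default 100 bp); the final
window of each chromosome is truncated at the chromosome end.  Each tag is
assigned to exactly one window — the window containing its interval midpoint
floor((start+end)/2) — so per-sample window counts always sum to the library
size (the conservation invariant relied on throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import TagSet


@dataclass
class WindowGrid:
    """Fixed-width tiling of a genome, chromosome-major order."""

    width: int
    chrom_sizes: dict[str, int]
    # derived
    chrom_order: list[str] = field(init=False)
    n_windows: dict[str, int] = field(init=False)
    offsets: dict[str, int] = field(init=False)  # ordinal of each chromosome's first window
    total_windows: int = field(init=False)

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"window width must be >= 1, got {self.width}")
        for chrom, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        self.chrom_order = list(self.chrom_sizes)
        self.n_windows = {c: -(-self.chrom_sizes[c] // self.width) for c in self.chrom_order}
        self.offsets = {}
        total = 0
        for c in self.chrom_order:
            self.offsets[c] = total
            total += self.n_windows[c]
        self.total_windows = total

    def window_bounds(self, ordinal: int) -> tuple[str, int, int]:
        """(chrom, start, end) of the window with the given global ordinal."""
        for c in self.chrom_order:
            if ordinal < self.offsets[c] + self.n_windows[c]:
                k = ordinal - self.offsets[c]
                start = k * self.width
                return c, start, min(start + self.width, self.chrom_sizes[c])
        raise IndexError(ordinal)

    def ordinal(self, chrom: str, position: int) -> int:
        """Global window ordinal containing a genomic position."""
        if chrom not in self.chrom_sizes:
            raise KeyError(chrom)
        if not 0 <= position < self.chrom_sizes[chrom]:
            raise ValueError(f"position {position} outside {chrom}")
        return self.offsets[chrom] + position // self.width

    def to_frame(self) -> pd.DataFrame:
        """Windows as a DataFrame with chrom/start/end columns."""
        chroms, starts, ends = [], [], []
        for c in self.chrom_order:
            n = self.n_windows[c]
            s = np.arange(n, dtype=np.int64) * self.width
            e = np.minimum(s + self.width, self.chrom_sizes[c])
            chroms.append(np.full(n, c, dtype=object))
            starts.append(s)
            ends.append(e)
        return pd.DataFrame(
            {
                "chrom": np.concatenate(chroms) if chroms else np.empty(0, dtype=object),
                "start": np.concatenate(starts) if starts else np.empty(0, dtype=np.int64),
                "end": np.concatenate(ends) if ends else np.empty(0, dtype=np.int64),
            }
        )

    def widths(self) -> np.ndarray:
        df = self.to_frame()
        return (df["end"] - df["start"]).to_numpy()


def tile_genome(chrom_sizes: Mapping[str, int], width: int = 100) -> WindowGrid:
    """Tile every chromosome into ceil(length/width) windows."""
    return WindowGrid(width=width, chrom_sizes=dict(chrom_sizes))


def count_tags(grid: WindowGrid, tagset: TagSet) -> np.ndarray:
    """Count tags per window by the midpoint rule.

    Every tag contributes exactly 1 to the window containing its midpoint,
    so the column sum equals the library size.  Tags on chromosomes not in
    the grid are an error (they should have been filtered at I/O).
    """
    counts = np.zeros(grid.total_windows, dtype=np.int64)
    if len(tagset) == 0:
        return counts
    mids = tagset.midpoints()
    chroms = tagset.chroms
    for chrom in np.unique(chroms.astype(str)):
        if chrom not in grid.chrom_sizes:
            raise ValueError(f"tag on unknown chromosome {chrom!r}")
        mask = chroms == chrom
        m = mids[mask]
        if (m < 0).any() or (m >= grid.chrom_sizes[chrom]).any():
            raise ValueError(f"tag midpoint outside chromosome {chrom}")
        ordinals = grid.offsets[chrom] + m // grid.width
        counts += np.bincount(ordinals, minlength=grid.total_windows)
    return counts


@dataclass
class CountMatrix:
    """Windows x samples tag counts with per-sample library sizes."""

    grid: WindowGrid
    counts: np.ndarray  # (n_windows, n_samples) int
    sample_labels: list[str]
    library_sizes: list[int]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.total_windows, len(self.sample_labels)):
            raise ValueError("counts shape does not match grid/samples")
        colsums = self.counts.sum(axis=0)
        if list(colsums) != list(self.library_sizes):
            raise ValueError("column sums do not equal library sizes (conservation violated)")

    def densities(self) -> np.ndarray:
        """Counts divided by actual window width (tags per bp), float."""
        return self.counts / self.grid.widths()[:, None]

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        for j, label in enumerate(self.sample_labels):
            df[f"count_{label}"] = self.counts[:, j]
        return df


def build_count_matrix(grid: WindowGrid, tagsets: Mapping[str, TagSet]) -> CountMatrix:
    """Count all samples on a shared grid; sample order follows the mapping."""
    labels = list(tagsets)
    cols = [count_tags(grid, tagsets[label]) for label in labels]
    counts = np.stack(cols, axis=1) if cols else np.zeros((grid.total_windows, 0), dtype=np.int64)
    return CountMatrix(
        grid=grid,
        counts=counts,
        sample_labels=labels,
        library_sizes=[tagsets[label].library_size for label in labels],
    )


def write_counts_tsv(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def write_bedgraph(matrix: CountMatrix, sample: str, path) -> None:
    """Per-sample density track (tags/bp) as bedGraph."""
    j = matrix.sample_labels.index(sample)
    df = matrix.grid.to_frame()
    df["value"] = matrix.densities()[:, j]
    df.to_csv(path, sep="\t", index=False, header=False)
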