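"""Segmentation of FDR-significant windows into directional regions.

A greedy single linear pass merges significant windows on the same
chromosome with the same direction whenever the gap between them is at most
``max_gap_windows`` x window width bp (default one intervening window
tolerated).  Opposite-direction windows never merge, even when adjacent.
Regions with fewer than ``min_windows`` constituent windows are dropped.
This equals the transitive closure of the pairwise "mergeable" relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Region:
    """Maximal run of same-direction significant windows."""

    chrom: str
    start: int
    end: int
    direction: str
    n_windows: int
    min_q: float
    mean_delta: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("region end must exceed start")


def segment(
    significant: pd.DataFrame,
    window_width: int,
    max_gap_windows: int = 1,
    min_windows: int = 1,
) -> list[Region]:
    """Merge significant windows into maximal same-direction regions.

    ``significant`` must be sorted by (chrom, start) and carry columns
    chrom, start, end, direction, q, delta.
    """
    if max_gap_windows < 0 or min_windows < 1:
        raise ValueError("max_gap_windows must be >= 0 and min_windows >= 1")
    if len(significant) == 0:
        return []
    chrom_col = significant["chrom"].to_numpy()
    start_col = significant["start"].to_numpy()
    for i in range(1, len(significant)):
        if chrom_col[i] == chrom_col[i - 1] and start_col[i] < start_col[i - 1]:
            raise ValueError("significant windows must be sorted by (chrom, start)")

    max_gap_bp = max_gap_windows * window_width
    regions: list[Region] = []
    # independent linear pass per (chrom, direction); sort=False keeps input order
    for (chrom, direction), grp in significant.groupby(["chrom", "direction"], sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        qs = grp["q"].to_numpy()
        deltas = grp["delta"].to_numpy()
        run = [0]
        for i in range(1, len(grp)):
            if starts[i] - ends[run[-1]] <= max_gap_bp:
                run.append(i)
            else:
                regions.append(_emit(chrom, direction, run, starts, ends, qs, deltas))
                run = [i]
        regions.append(_emit(chrom, direction, run, starts, ends, qs, deltas))
    regions = [r for r in regions if r.n_windows >= min_windows]
    regions.sort(key=lambda r: (r.chrom, r.start, r.direction))
    return regions


def _emit(chrom, direction, run, starts, ends, qs, deltas) -> Region:
    idx = np.asarray(run)
    return Region(
        chrom=str(chrom),
        start=int(starts[idx].min()),
        end=int(ends[idx].max()),
        direction=str(direction),
        n_windows=len(idx),
        min_q=float(qs[idx].min()),
        mean_delta=float(deltas[idx].mean()),
    )


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "direction": r.direction,
                "n_windows": r.n_windows,
                "min_q": r.min_q,
                "mean_delta": r.mean_delta,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "direction", "n_windows", "min_q", "mean_delta"],
    )


def write_regions_bed(regions: list[Region], path) -> None:
    """BED6: name = direction, score = round(-10*log10(min_q)) capped at 1000."""
    with open(path, "w") as fh:
        for r in regions:
            if r.min_q <= 0:
                score = 1000
            else:
                score = min(1000, int(round(-10.0 * np.log10(r.min_q))))
            score = max(0, score)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t{score}\t.\n")


def write_regions_tsv(regions: list[Region], path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)
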