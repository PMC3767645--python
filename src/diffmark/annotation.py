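"""Feature-class annotation of differential regions.

Classifies each feature (CpG island, promoter, ...) by the directions of the
differential regions it overlaps (>= 1 bp, half-open semantics), computes
directional percentages over the differential features of each class, and
compares tag occupation between conditions per class as a library-scaled
ratio (tags per million in condition B over condition A), the tag-level
statistic computed before any windowing or quantile normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import FeatureSet, TagSet
from .segmentation import Region

LABEL_B = "higher_in_B"
LABEL_A = "higher_in_A"
LABEL_MIXED = "mixed"
LABEL_UNCHANGED = "unchanged"


def _region_trees(regions: list[Region]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.direction)
    return trees


def classify_features(features: FeatureSet, regions: list[Region]) -> pd.DataFrame:
    """Label each feature by the directions of overlapping regions.

    higher_in_B / higher_in_A when only regions of that one direction
    overlap; mixed when both directions overlap; unchanged when none do.
    """
    trees = _region_trees(regions)
    rows = []
    for chrom, start, end, fid in features:
        hits = trees[chrom].overlap(start, end) if chrom in trees else ()
        dirs = {iv.data for iv in hits}
        if not dirs:
            label = LABEL_UNCHANGED
        elif dirs == {LABEL_B}:
            label = LABEL_B
        elif dirs == {LABEL_A}:
            label = LABEL_A
        else:
            label = LABEL_MIXED
        rows.append({"feature_id": fid, "class_name": features.class_name, "label": label})
    return pd.DataFrame(rows, columns=["feature_id", "class_name", "label"])


def directional_percentages(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-class percentages over DIFFERENTIAL features (label != unchanged).

    Classes with no differential feature get NaN percentages (not
    applicable).  Within a class the three percentages sum to 100.
    """
    rows = []
    for class_name, grp in labels.groupby("class_name", sort=False):
        diff = grp[grp["label"] != LABEL_UNCHANGED]
        n = len(diff)
        row = {"class_name": class_name, "n_features": len(grp), "n_differential": n}
        if n == 0:
            row.update(pct_higher_in_B=np.nan, pct_higher_in_A=np.nan, pct_mixed=np.nan)
        else:
            row.update(
                pct_higher_in_B=100.0 * (diff["label"] == LABEL_B).sum() / n,
                pct_higher_in_A=100.0 * (diff["label"] == LABEL_A).sum() / n,
                pct_mixed=100.0 * (diff["label"] == LABEL_MIXED).sum() / n,
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["class_name", "n_features", "n_differential", "pct_higher_in_B", "pct_higher_in_A", "pct_mixed"],
    )


def _merged_intervals(features: FeatureSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union-merge class intervals per chromosome -> sorted (starts, ends)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _ in features:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        starts = np.array([s for s, _ in out], dtype=np.int64)
        ends = np.array([e for _, e in out], dtype=np.int64)
        merged[chrom] = (starts, ends)
    return merged


def _tags_in_class(features: FeatureSet, tagset: TagSet) -> int:
    """Tags whose midpoint falls inside the class's union-merged intervals."""
    merged = _merged_intervals(features)
    mids = tagset.midpoints()
    total = 0
    for chrom, (starts, ends) in merged.items():
        m = mids[tagset.chroms == chrom]
        if m.size == 0:
            continue
        idx = np.searchsorted(starts, m, side="right") - 1
        ok = idx >= 0
        total += int((m[ok] < ends[idx[ok]]).sum())
    return total


def occupation_ratio(features: FeatureSet, tags_A: TagSet, tags_B: TagSet) -> dict:
    """Library-scaled tag-occupation summary for one feature class.

    rate = in-class tags per million library tags; ratio = rate_B / rate_A.
    The ratio is flagged undefined (NaN) when rate_A == 0 or the class is
    empty.
    """
    if tags_A.library_size < 1 or tags_B.library_size < 1:
        raise ValueError("library sizes must be >= 1")
    in_a = _tags_in_class(features, tags_A) if len(features) else 0
    in_b = _tags_in_class(features, tags_B) if len(features) else 0
    rate_a = 1e6 * in_a / tags_A.library_size
    rate_b = 1e6 * in_b / tags_B.library_size
    ratio = rate_b / rate_a if rate_a > 0 else float("nan")
    return {
        "class_name": features.class_name,
        "tags_A": in_a,
        "tags_B": in_b,
        "rate_A": rate_a,
        "rate_B": rate_b,
        "ratio": ratio,
    }


def occupation_summary(feature_sets: list[FeatureSet], tags_A: TagSet, tags_B: TagSet) -> pd.DataFrame:
    return pd.DataFrame(
        [occupation_ratio(fs, tags_A, tags_B) for fs in feature_sets],
        columns=["class_name", "tags_A", "tags_B", "rate_A", "rate_B", "ratio"],
    )


def summarize_by_chromosome(regions: list[Region]) -> pd.DataFrame:
    """chrom x direction region counts (the per-chromosome differential map)."""
    if not regions:
        return pd.DataFrame(columns=["chrom", LABEL_B, LABEL_A]).astype({LABEL_B: int, LABEL_A: int})
    rows: dict[str, dict[str, int]] = {}
    for r in regions:
        rec = rows.setdefault(r.chrom, {LABEL_B: 0, LABEL_A: 0})
        rec[r.direction] += 1
    out = pd.DataFrame(
        [{"chrom": c, LABEL_B: v[LABEL_B], LABEL_A: v[LABEL_A]} for c, v in sorted(rows.items())],
        columns=["chrom", LABEL_B, LABEL_A],
    )
    return out
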