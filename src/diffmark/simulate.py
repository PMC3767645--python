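"""Synthetic two-condition ChIP-seq tag simulator with planted enrichment.

Emulates the study design the pipeline targets: two single-library
conditions (A plays wild-type ES, B plays the Dicer-null mutant) on a toy
genome, with tag start positions following a per-bp Poisson law at a uniform
background rate, and a multiplicative rate increase over a planted subset of
CpG-island intervals in condition B only (matching the observed direction of
increased H3K9me2 in the mutant).  Strand is assigned uniformly at random;
nothing downstream uses it.

Defaults describe the desk-scale study conditions: a 2 x 1 Mb genome,
background 0.01 tags/bp per library (about one tag per 100 bp window, the
order of a real mammalian ChIP-seq library's genome-wide tag density),
100 islands of 500 bp with half planted at fold 4.

Deliberately NOT modeled: fragment-size distributions, PCR duplicates,
mappability bias, and input/control libraries (the emulated design has
none).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import FeatureSet, TagSet

DIRECTION_B = "higher_in_B"
DIRECTION_NONE = "none"

CONDITION_STREAM = {"A": 1, "B": 2}
LAYOUT_STREAM = 0


class LayoutError(ValueError):
    """Requested features cannot be placed within the chromosome bounds."""


@dataclass
class SimConfig:
    """Parameters of the synthetic two-condition experiment."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    n_islands: int = 100
    island_len_bp: int = 500
    n_promoters: int = 50
    promoter_len_bp: int = 1000
    n_exons: int = 200
    exon_len_bp: int = 200
    background_rate: float = 0.01  # expected tags per bp per library
    enrich_fold: float = 4.0
    frac_planted: float = 0.5
    tag_len_bp: int = 36
    depth_scale_A: float = 1.0
    depth_scale_B: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("island_len_bp", "promoter_len_bp", "exon_len_bp", "tag_len_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_islands", "n_promoters", "n_exons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_planted <= 1.0:
            raise ValueError("frac_planted must lie in [0, 1]")
        if self.enrich_fold <= 0:
            raise ValueError("enrich_fold must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.depth_scale_A < 0 or self.depth_scale_B < 0:
            raise ValueError("depth scales must be >= 0")
        for chrom, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TruthSet:
    """Ground truth for every island: direction and true rate fold in B."""

    table: pd.DataFrame  # feature_id, direction, fold

    def __post_init__(self):
        expected = {"feature_id", "direction", "fold"}
        if set(self.table.columns) != expected:
            raise ValueError(f"truth table must have columns {sorted(expected)}")

    @property
    def planted(self) -> pd.DataFrame:
        return self.table[self.table["fold"] != 1.0].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthSet":
        return cls(pd.read_csv(path, sep="\t"))


def _place_class(rng, chrom_sizes, n: int, length: int, class_name: str) -> list[tuple]:
    """Place n non-overlapping length-bp intervals, allocated to chromosomes
    proportionally to their lengths, uniformly at random given the seed."""
    if n == 0:
        return []
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    # proportional allocation by largest remainder
    quota = n * sizes / sizes.sum()
    alloc = np.floor(quota).astype(int)
    rem = n - alloc.sum()
    if rem:
        alloc[np.argsort(quota - np.floor(quota))[::-1][:rem]] += 1
    intervals = []
    i = 0
    for chrom, k in zip(chroms, alloc):
        L = chrom_sizes[chrom]
        if k * length > L:
            raise LayoutError(
                f"cannot place {k} non-overlapping {class_name} intervals of {length} bp on {chrom} ({L} bp)"
            )
        if k == 0:
            continue
        # spacings construction: uniform non-overlapping placement
        slack = rng.integers(0, L - k * length + 1, size=k)
        slack.sort()
        starts = slack + np.arange(k) * length
        for s in starts:
            i += 1
            intervals.append((chrom, int(s), int(s + length), f"{class_name}_{i}"))
    return intervals


def build_toy_layout(config: SimConfig) -> tuple[dict[str, FeatureSet], TruthSet]:
    """Generate the feature catalog and the planted ground truth.

    Features are non-overlapping within a class but may overlap across
    classes, as in a real genome.  Deterministic given the config seed.
    """
    rng = np.random.default_rng([config.seed, LAYOUT_STREAM])
    catalog = {
        "cpg_island": FeatureSet("cpg_island", _place_class(rng, config.chrom_sizes, config.n_islands, config.island_len_bp, "cpg_island")),
        "promoter": FeatureSet("promoter", _place_class(rng, config.chrom_sizes, config.n_promoters, config.promoter_len_bp, "promoter")),
        "exon": FeatureSet("exon", _place_class(rng, config.chrom_sizes, config.n_exons, config.exon_len_bp, "exon")),
    }
    island_ids = [fid for _, _, _, fid in catalog["cpg_island"]]
    n_planted = round(config.frac_planted * config.n_islands)
    planted_ids = set(rng.choice(island_ids, size=n_planted, replace=False)) if n_planted else set()
    truth = TruthSet(
        pd.DataFrame(
            {
                "feature_id": island_ids,
                "direction": [DIRECTION_B if fid in planted_ids else DIRECTION_NONE for fid in island_ids],
                "fold": [config.enrich_fold if fid in planted_ids else 1.0 for fid in island_ids],
            }
        )
    )
    return catalog, truth


def simulate_tags(config: SimConfig, catalog: dict[str, FeatureSet], truth: TruthSet, condition: str) -> TagSet:
    """Draw one condition's tag library.

    Tag starts follow a per-bp Poisson law at background_rate x depth_scale;
    within a planted island, condition B's rate is multiplied by the true
    fold (implemented by Poisson superposition of the extra rate over the
    island).  Tags are tag_len_bp intervals clipped at chromosome ends.
    """
    if condition not in CONDITION_STREAM:
        raise ValueError(f"unknown condition {condition!r}; expected one of {sorted(CONDITION_STREAM)}")
    rng = np.random.default_rng([config.seed, CONDITION_STREAM[condition]])
    depth = config.depth_scale_A if condition == "A" else config.depth_scale_B
    base = config.background_rate * depth

    chrom_col, start_col = [], []
    for chrom, length in config.chrom_sizes.items():
        n = rng.poisson(base * length)
        if n:
            chrom_col.append(np.full(n, chrom, dtype=object))
            start_col.append(rng.integers(0, length, size=n))
    if condition == "B" and base > 0:
        fold_by_id = dict(zip(truth.table["feature_id"], truth.table["fold"]))
        for chrom, s, e, fid in catalog.get("cpg_island", FeatureSet("cpg_island")):
            fold = fold_by_id.get(fid, 1.0)
            extra_rate = base * (fold - 1.0)
            if extra_rate <= 0:
                continue
            n = rng.poisson(extra_rate * (e - s))
            if n:
                chrom_col.append(np.full(n, chrom, dtype=object))
                start_col.append(rng.integers(s, e, size=n))
    if not chrom_col:
        return TagSet.empty()
    chroms = np.concatenate(chrom_col)
    starts = np.concatenate(start_col).astype(np.int64)
    lengths = np.array([config.chrom_sizes[c] for c in chroms], dtype=np.int64)
    ends = np.minimum(starts + config.tag_len_bp, lengths)
    strands = np.where(rng.random(len(starts)) < 0.5, "+", "-").astype(object)
    # canonical order so identical configs give byte-identical BED output
    order = np.lexsort((starts, chroms.astype(str)))
    return TagSet(chroms[order], starts[order], ends[order], strands[order])
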