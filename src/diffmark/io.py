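"""Tag and feature I/O.

Aligned sequencing tags are read from BED (3-6 columns) or SAM; genomic
feature classes (CpG islands, promoters, exons, ...) from BED.  All internal
coordinates are 0-based half-open (BED convention); SAM's 1-based positions
are converted on ingest.

"Uniquely mapping" reads are operationalized as mapped records with
MAPQ >= ``mapq_min`` (default 20) and, when an NH tag is present, NH == 1.
Duplicate identical tags are kept: no deduplication is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

FEATURE_CLASSES = (
    "cpg_island",
    "promoter",
    "exon",
    "intron",
    "whole_gene",
    "utr3",
    "mirna_cluster",
    "pirna_cluster",
    "custom",
)


class TagFileError(ValueError):
    """Malformed tag/feature file; carries the offending line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True)
class AlignedTag:
    """One uniquely-mapped sequencing tag as a genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid tag interval [{self.start}, {self.end})")


@dataclass
class TagSet:
    """Columnar collection of aligned tags for one sequencing library.

    ``library_size`` is the number of tags, by construction.
    """

    chroms: np.ndarray  # dtype=object, chromosome name per tag
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    strands: np.ndarray  # dtype=object, one of '+', '-', '.'

    def __post_init__(self):
        n = len(self.starts)
        if not (len(self.chroms) == len(self.ends) == len(self.strands) == n):
            raise ValueError("TagSet columns have unequal lengths")

    @property
    def library_size(self) -> int:
        return len(self.starts)

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[AlignedTag]:
        for c, s, e, st in zip(self.chroms, self.starts, self.ends, self.strands):
            yield AlignedTag(str(c), int(s), int(e), str(st))

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "TagSet":
        """Build from (chrom, start, end[, strand]) tuples or AlignedTags."""
        rows = []
        for r in records:
            if isinstance(r, AlignedTag):
                rows.append((r.chrom, r.start, r.end, r.strand))
            else:
                chrom, start, end = r[:3]
                strand = r[3] if len(r) > 3 else "."
                rows.append((chrom, start, end, strand))
        if not rows:
            return cls.empty()
        chroms, starts, ends, strands = zip(*rows)
        return cls(
            np.array(chroms, dtype=object),
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
            np.array(strands, dtype=object),
        )

    @classmethod
    def empty(cls) -> "TagSet":
        return cls(
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=object),
        )

    def midpoints(self) -> np.ndarray:
        """Integer midpoint floor((start+end)/2) of each tag."""
        return (self.starts + self.ends) // 2


@dataclass
class FeatureSet:
    """A labeled class of genomic intervals (e.g. all CpG islands)."""

    class_name: str
    intervals: list = field(default_factory=list)  # (chrom, start, end, feature_id)

    def __post_init__(self):
        self.intervals = sorted(self.intervals, key=lambda iv: (iv[0], iv[1], iv[2]))
        seen: set[str] = set()
        for _, _, _, fid in self.intervals:
            if fid in seen:
                raise ValueError(f"duplicate feature_id {fid!r} in class {self.class_name!r}")
            seen.add(fid)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV into an ordered dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise TagFileError(path, lineno, "expected <chrom>\\t<length>")
            try:
                length = int(parts[1])
            except ValueError:
                raise TagFileError(path, lineno, f"non-integer length {parts[1]!r}") from None
            if length <= 0:
                raise TagFileError(path, lineno, f"non-positive chromosome length {length}")
            sizes[parts[0]] = length
    return sizes


def _parse_bed_line(path, lineno: int, line: str, min_cols: int = 3):
    parts = line.rstrip("\n").split("\t")
    if len(parts) < min_cols:
        raise TagFileError(path, lineno, f"expected >= {min_cols} tab-separated columns, got {len(parts)}")
    chrom = parts[0]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError:
        raise TagFileError(path, lineno, f"non-integer coordinates {parts[1]!r}, {parts[2]!r}") from None
    if start < 0 or start >= end:
        raise TagFileError(path, lineno, f"invalid interval [{start}, {end}) (need 0 <= start < end)")
    return chrom, start, end, parts


def read_tags_bed(path, chrom_sizes: Mapping[str, int] | None = None) -> TagSet:
    """Read aligned tags from a >=3-column BED file.

    Tags on chromosomes absent from ``chrom_sizes`` (when supplied) are
    rejected with a logged count; coordinates beyond chromosome ends are a
    parse error.  An empty file yields an empty TagSet with a warning.
    """
    chroms, starts, ends, strands = [], [], [], []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, parts = _parse_bed_line(path, lineno, line)
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    n_rejected += 1
                    continue
                if end > chrom_sizes[chrom]:
                    raise TagFileError(path, lineno, f"interval end {end} beyond {chrom} length {chrom_sizes[chrom]}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    if n_rejected:
        logger.info("%s: rejected %d tags on unknown chromosomes", path, n_rejected)
    if not starts:
        logger.warning("%s: no tags read", path)
        return TagSet.empty()
    return TagSet(
        np.array(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.array(strands, dtype=object),
    )


def read_tags_sam(path, mapq_min: int = 20, chrom_sizes: Mapping[str, int] | None = None) -> TagSet:
    """Read uniquely-mapping tags from a SAM file.

    Keeps mapped records with MAPQ >= ``mapq_min``; records carrying an NH
    tag must additionally have NH == 1.  A missing header is an error; a
    file with only unmapped reads yields an empty TagSet with a warning.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if not sam.header.get("SQ") and chrom_sizes is None:
            raise TagFileError(path, None, "SAM header has no @SQ lines and no chrom_sizes supplied")
        chroms, starts, ends, strands = [], [], [], []
        n_rejected = 0
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            if rec.has_tag("NH") and rec.get_tag("NH") != 1:
                continue
            chrom = rec.reference_name
            if chrom_sizes is not None and chrom not in chrom_sizes:
                n_rejected += 1
                continue
            chroms.append(chrom)
            starts.append(rec.reference_start)  # pysam is already 0-based
            ends.append(rec.reference_end)
            strands.append("-" if rec.is_reverse else "+")
    if n_rejected:
        logger.info("%s: rejected %d tags on unknown chromosomes", path, n_rejected)
    if not starts:
        logger.warning("%s: no uniquely mapping tags passed filters", path)
        return TagSet.empty()
    return TagSet(
        np.array(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.array(strands, dtype=object),
    )


def read_features_bed(path, class_name: str) -> FeatureSet:
    """Read one feature class from BED; auto-names features when column 4 is absent."""
    intervals = []
    auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, parts = _parse_bed_line(path, lineno, line)
            if len(parts) >= 4 and parts[3]:
                fid = parts[3]
            else:
                auto += 1
                fid = f"{class_name}_{auto}"
            intervals.append((chrom, start, end, fid))
    try:
        return FeatureSet(class_name=class_name, intervals=intervals)
    except ValueError as exc:
        raise TagFileError(path, None, str(exc)) from None


def write_tags_bed(tagset: TagSet, path) -> None:
    """Write tags as 6-column BED (name=t<i>, score=0)."""
    with open(path, "w") as fh:
        for i, (c, s, e, st) in enumerate(zip(tagset.chroms, tagset.starts, tagset.ends, tagset.strands), 1):
            strand = st if st in "+-" else "."
            fh.write(f"{c}\t{s}\t{e}\tt{i}\t0\t{strand}\n")


def write_features_bed(features: FeatureSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, fid in features:
            fh.write(f"{chrom}\t{start}\t{end}\t{fid}\n")


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
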