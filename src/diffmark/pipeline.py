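"""End-to-end orchestration: ingest, count, normalize, test, segment, annotate.

``run_pipeline`` executes the whole analysis deterministically from a
RunConfig, writing every output table plus a manifest (config, package
version, input checksums) under one directory; ``report`` renders a
human-readable summary from a completed output bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import classify_features, directional_percentages, occupation_summary, summarize_by_chromosome
from .differential import select_windows, differential_table
from .io import read_chrom_sizes, read_features_bed, read_tags_bed, read_tags_sam
from .normalize import cpm_normalize, quantile_normalize
from .segmentation import segment, write_regions_bed, write_regions_tsv
from .windows import build_count_matrix, tile_genome, write_counts_tsv

logger = logging.getLogger(__name__)

OUTPUT_FILES = {
    "counts": "window_counts.tsv",
    "differential": "differential_windows.tsv",
    "regions_bed": "regions.bed",
    "regions_tsv": "regions.tsv",
    "feature_labels": "feature_labels.tsv",
    "directional": "directional_percentages.tsv",
    "occupation": "occupation_summary.tsv",
    "chromosomes": "chromosome_summary.tsv",
    "manifest": "manifest.json",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    tags_a: str
    tags_b: str
    chrom_sizes: str
    features: dict[str, str] = field(default_factory=dict)  # class_name -> BED path
    tag_format: str = "bed"  # bed | sam
    mapq_min: int = 20
    window_width: int = 100
    normalization: str = "quantile"  # quantile | cpm | none
    test: str = "binomial"
    fdr: float = 0.001
    max_gap_windows: int = 1
    min_windows: int = 1
    output_dir: str = "diffmark_out"
    seed: int = 0  # reserved for stochastic stages; the core pipeline is deterministic

    def __post_init__(self):
        if self.tag_format not in ("bed", "sam"):
            raise ValueError(f"unknown tag format {self.tag_format!r}")
        if self.normalization not in ("quantile", "cpm", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.test != "binomial":
            raise ValueError(f"unknown test {self.test!r}")
        if not 0 <= self.fdr <= 1:
            raise ValueError("fdr must lie in [0, 1]")
        if self.window_width < 1:
            raise ValueError("window_width must be >= 1")

    def validate_paths(self) -> None:
        for label, path in [("tags_a", self.tags_a), ("tags_b", self.tags_b), ("chrom_sizes", self.chrom_sizes)] + [
            (f"features[{k}]", v) for k, v in self.features.items()
        ]:
            if not Path(path).exists():
                raise FileNotFoundError(f"{label}: no such file {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_tags(config: RunConfig, path, sizes):
    if config.tag_format == "sam":
        return read_tags_sam(path, mapq_min=config.mapq_min, chrom_sizes=sizes)
    return read_tags_bed(path, chrom_sizes=sizes)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full differential analysis; returns the output bundle paths."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {key: outdir / name for key, name in OUTPUT_FILES.items()}

    stage = "ingest"
    try:
        sizes = read_chrom_sizes(config.chrom_sizes)
        tags_a = _read_tags(config, config.tags_a, sizes)
        tags_b = _read_tags(config, config.tags_b, sizes)
        logger.info("ingest: %d tags in A, %d tags in B", tags_a.library_size, tags_b.library_size)
        if tags_a.library_size == 0:
            raise PipelineError(f"ingest: no tags read from condition A input {config.tags_a}")
        if tags_b.library_size == 0:
            raise PipelineError(f"ingest: no tags read from condition B input {config.tags_b}")
        feature_sets = [read_features_bed(path, class_name) for class_name, path in config.features.items()]

        stage = "windowing"
        grid = tile_genome(sizes, width=config.window_width)
        matrix = build_count_matrix(grid, {"A": tags_a, "B": tags_b})
        write_counts_tsv(matrix, paths["counts"])
        logger.info("windowing: %d windows (%d bp)", grid.total_windows, config.window_width)

        stage = "normalization"
        dens = matrix.densities()
        if config.normalization == "quantile":
            norm = quantile_normalize(dens)
        elif config.normalization == "cpm":
            norm = cpm_normalize(matrix.counts, matrix.library_sizes)
        else:
            norm = dens

        stage = "differential"
        table = differential_table(matrix, norm)
        table.to_csv(paths["differential"], sep="\t", index=False, float_format="%.6g")
        significant = select_windows(table, q_threshold=config.fdr)
        logger.info(
            "differential: %d tested, %d significant at q<%g (%d higher_in_B, %d higher_in_A)",
            len(table),
            len(significant),
            config.fdr,
            (significant["direction"] == "higher_in_B").sum(),
            (significant["direction"] == "higher_in_A").sum(),
        )

        stage = "segmentation"
        regions = segment(
            significant,
            window_width=config.window_width,
            max_gap_windows=config.max_gap_windows,
            min_windows=config.min_windows,
        )
        write_regions_bed(regions, paths["regions_bed"])
        write_regions_tsv(regions, paths["regions_tsv"])
        logger.info("segmentation: %d regions", len(regions))

        stage = "annotation"
        labels = (
            pd.concat([classify_features(fs, regions) for fs in feature_sets], ignore_index=True)
            if feature_sets
            else pd.DataFrame(columns=["feature_id", "class_name", "label"])
        )
        labels.to_csv(paths["feature_labels"], sep="\t", index=False)
        directional_percentages(labels).to_csv(paths["directional"], sep="\t", index=False, float_format="%.4g")
        occupation_summary(feature_sets, tags_a, tags_b).to_csv(
            paths["occupation"], sep="\t", index=False, float_format="%.6g"
        )
        summarize_by_chromosome(regions).to_csv(paths["chromosomes"], sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    manifest = {
        "package": "diffmark",
        "version": __version__,
        "config": asdict(config),
        "inputs": {
            "tags_a": _sha256(config.tags_a),
            "tags_b": _sha256(config.tags_b),
            "chrom_sizes": _sha256(config.chrom_sizes),
            "features": {k: _sha256(v) for k, v in config.features.items()},
        },
        "outputs": {k: str(v) for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths


def report(output_dir) -> str:
    """Render a plain-text summary of a completed run's output bundle."""
    outdir = Path(output_dir)
    for key in ("differential", "regions_tsv", "occupation", "chromosomes"):
        if not (outdir / OUTPUT_FILES[key]).exists():
            raise FileNotFoundError(f"missing bundle file {OUTPUT_FILES[key]} under {outdir}")
    table = pd.read_csv(outdir / OUTPUT_FILES["differential"], sep="\t")
    regions = pd.read_csv(outdir / OUTPUT_FILES["regions_tsv"], sep="\t")
    occupation = pd.read_csv(outdir / OUTPUT_FILES["occupation"], sep="\t")
    chrom = pd.read_csv(outdir / OUTPUT_FILES["chromosomes"], sep="\t")

    manifest_path = outdir / OUTPUT_FILES["manifest"]
    fdr = None
    if manifest_path.exists():
        with open(manifest_path) as fh:
            fdr = json.load(fh)["config"].get("fdr")
    sig = table[table["q"] < fdr] if fdr is not None else table[table["q"] < 0.001]

    lines = ["diffmark run summary", "====================", ""]
    lines.append(f"tested windows:      {len(table)}")
    lines.append(f"significant windows: {len(sig)}")
    lines.append(f"  higher_in_B:       {(sig['direction'] == 'higher_in_B').sum()}")
    lines.append(f"  higher_in_A:       {(sig['direction'] == 'higher_in_A').sum()}")
    lines.append(f"regions:             {len(regions)}")
    lines.append("")
    lines.append("per-chromosome region counts:")
    lines.append(chrom.to_string(index=False) if len(chrom) else "  (no regions)")
    lines.append("")
    lines.append("occupation ratios (B/A, tags per million), descending:")
    if len(occupation):
        ordered = occupation.sort_values("ratio", ascending=False, na_position="last")
        lines.append(ordered.to_string(index=False))
    else:
        lines.append("  (no feature classes supplied)")
    return "\n".join(lines) + "\n"
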