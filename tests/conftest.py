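import numpy as np
import pytest

from diffmark import SimConfig, build_toy_layout, simulate_tags
from diffmark.windows import build_count_matrix, tile_genome


@pytest.fixture
def tiny_sizes():
    return {"chr1": 10_000, "chr2": 5_000}


@pytest.fixture
def small_config(tiny_sizes):
    """A small but non-degenerate simulated experiment."""
    return SimConfig(
        chrom_sizes=tiny_sizes,
        n_islands=6,
        island_len_bp=400,
        n_promoters=4,
        n_exons=8,
        exon_len_bp=150,
        background_rate=0.02,
        enrich_fold=8.0,
        frac_planted=0.5,
        seed=11,
    )


@pytest.fixture
def small_dataset(small_config):
    catalog, truth = build_toy_layout(small_config)
    tags_a = simulate_tags(small_config, catalog, truth, "A")
    tags_b = simulate_tags(small_config, catalog, truth, "B")
    return small_config, catalog, truth, tags_a, tags_b


@pytest.fixture
def small_matrix(small_dataset):
    config, _, _, tags_a, tags_b = small_dataset
    grid = tile_genome(config.chrom_sizes, width=100)
    return build_count_matrix(grid, {"A": tags_a, "B": tags_b})


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
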