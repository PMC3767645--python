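import numpy as np
import pandas as pd
import pytest

from diffmark.annotation import (
    classify_features,
    directional_percentages,
    occupation_ratio,
    occupation_summary,
    summarize_by_chromosome,
)
from diffmark.io import FeatureSet, TagSet
from diffmark.segmentation import Region


def region(chrom, start, end, direction):
    return Region(chrom, start, end, direction, n_windows=1, min_q=1e-6, mean_delta=1.0 if direction.endswith("B") else -1.0)


class TestClassify:
    def test_single_direction_overlap_labels_feature(self):
        fs = FeatureSet("cpg_island", [("chr1", 50, 150, "cgi1")])
        out = classify_features(fs, [region("chr1", 100, 200, "higher_in_B")])
        assert list(out["label"]) == ["higher_in_B"]

    def test_both_directions_give_mixed(self):
        fs = FeatureSet("cpg_island", [("chr1", 50, 350, "cgi1")])
        regions = [region("chr1", 0, 100, "higher_in_B"), region("chr1", 300, 400, "higher_in_A")]
        assert list(classify_features(fs, regions)["label"]) == ["mixed"]

    def test_half_open_boundary_touch_is_not_overlap(self):
        fs = FeatureSet("cpg_island", [("chr1", 0, 100, "cgi1")])
        assert list(classify_features(fs, [region("chr1", 100, 200, "higher_in_B")])["label"]) == ["unchanged"]

    def test_agrees_with_all_pairs_oracle(self, rng):
        for _ in range(100):
            n_feat, n_reg = int(rng.integers(1, 15)), int(rng.integers(0, 15))
            feats = []
            for i in range(n_feat):
                chrom = f"chr{int(rng.integers(1, 3))}"
                s = int(rng.integers(0, 900))
                feats.append((chrom, s, s + int(rng.integers(1, 120)), f"f{i}"))
            regions = []
            for _j in range(n_reg):
                chrom = f"chr{int(rng.integers(1, 3))}"
                s = int(rng.integers(0, 900))
                d = "higher_in_B" if rng.random() < 0.5 else "higher_in_A"
                regions.append(region(chrom, s, s + int(rng.integers(1, 120)), d))
            fs = FeatureSet("custom", feats)
            got = classify_features(fs, regions).set_index("feature_id")["label"]
            for chrom, s, e, fid in feats:
                dirs = {r.direction for r in regions if r.chrom == chrom and s < r.end and r.start < e}
                expected = (
                    "unchanged" if not dirs else "mixed" if len(dirs) == 2 else next(iter(dirs))
                )
                assert got[fid] == expected


class TestDirectionalPercentages:
    def make_labels(self, counts):
        rows = []
        for label, k in counts.items():
            rows += [{"feature_id": f"{label}{i}", "class_name": "cpg_island", "label": label} for i in range(k)]
        return pd.DataFrame(rows)

    def test_percentages_over_differential_features_only(self):
        labels = self.make_labels({"higher_in_B": 98, "higher_in_A": 2, "unchanged": 100})
        out = directional_percentages(labels)
        assert out.loc[0, "pct_higher_in_B"] == pytest.approx(98.0)
        assert out.loc[0, "pct_higher_in_A"] == pytest.approx(2.0)
        assert out.loc[0, "n_differential"] == 100

    def test_all_unchanged_is_not_applicable(self):
        out = directional_percentages(self.make_labels({"unchanged": 5}))
        assert np.isnan(out.loc[0, "pct_higher_in_B"])

    def test_single_differential_feature_is_100_percent(self):
        out = directional_percentages(self.make_labels({"higher_in_B": 1}))
        assert out.loc[0, "pct_higher_in_B"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        out = directional_percentages(self.make_labels({"higher_in_B": 3, "higher_in_A": 2, "mixed": 2}))
        total = out[["pct_higher_in_B", "pct_higher_in_A", "pct_mixed"]].sum(axis=1)
        assert total.iloc[0] == pytest.approx(100.0)


def uniform_tags(rng, chrom, lo, hi, n, length=36):
    starts = rng.integers(lo, hi, size=n)
    return [(chrom, int(s), int(s) + length) for s in starts]


class TestOccupation:
    def test_identical_tagsets_give_unit_ratio(self, rng):
        ts = TagSet.from_records(uniform_tags(rng, "chr1", 0, 900, 50))
        fs = FeatureSet("cpg_island", [("chr1", 0, 1000, "cgi1")])
        assert occupation_ratio(fs, ts, ts)["ratio"] == pytest.approx(1.0)

    def test_doubled_in_class_tags_at_equal_depth_give_ratio_two(self):
        fs = FeatureSet("cpg_island", [("chr1", 0, 100, "cgi1")])
        inside = [("chr1", 10, 46)]
        outside = [("chr1", 500, 536)]
        a = TagSet.from_records(inside + outside * 3)
        b = TagSet.from_records(inside * 2 + outside * 2)
        out = occupation_ratio(fs, a, b)
        assert out["tags_A"] == 1 and out["tags_B"] == 2
        assert out["ratio"] == pytest.approx(2.0)

    def test_empty_class_flags_undefined_ratio(self):
        ts = TagSet.from_records([("chr1", 0, 36)])
        out = occupation_ratio(FeatureSet("mirna_cluster", []), ts, ts)
        assert out["tags_A"] == 0 and np.isnan(out["ratio"])

    def test_invariant_to_splitting_an_interval(self, rng):
        tags_a = TagSet.from_records(uniform_tags(rng, "chr1", 0, 2000, 200))
        tags_b = TagSet.from_records(uniform_tags(rng, "chr1", 0, 2000, 300))
        whole = FeatureSet("cpg_island", [("chr1", 400, 800, "cgi1")])
        split = FeatureSet("cpg_island", [("chr1", 400, 600, "l"), ("chr1", 600, 800, "r")])
        r1, r2 = occupation_ratio(whole, tags_a, tags_b), occupation_ratio(split, tags_a, tags_b)
        assert r1["tags_A"] == r2["tags_A"] and r1["tags_B"] == r2["tags_B"]

    def test_overlapping_intervals_union_merged_not_double_counted(self):
        fs = FeatureSet("cpg_island", [("chr1", 0, 100, "a"), ("chr1", 50, 150, "b")])
        ts = TagSet.from_records([("chr1", 60, 96)])  # midpoint 78, inside both
        assert occupation_ratio(fs, ts, ts)["tags_A"] == 1

    def test_summary_stacks_classes(self, rng):
        ts = TagSet.from_records(uniform_tags(rng, "chr1", 0, 900, 40))
        sets = [FeatureSet("cpg_island", [("chr1", 0, 500, "c1")]), FeatureSet("exon", [("chr1", 500, 900, "e1")])]
        out = occupation_summary(sets, ts, ts)
        assert list(out["class_name"]) == ["cpg_island", "exon"]


class TestChromosomeSummary:
    def test_empty_regions_give_empty_table(self):
        assert len(summarize_by_chromosome([])) == 0

    def test_counts_by_direction(self):
        regions = [
            region("chr1", 0, 100, "higher_in_B"),
            region("chr1", 300, 400, "higher_in_B"),
            region("chr1", 600, 700, "higher_in_A"),
            region("chr2", 0, 100, "higher_in_A"),
        ]
        out = summarize_by_chromosome(regions).set_index("chrom")
        assert out.loc["chr1", "higher_in_B"] == 2
        assert out.loc["chr1", "higher_in_A"] == 1
        assert int(out.to_numpy().sum()) == len(regions)
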