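import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methrev.io import GenomicInterval, cov_col, meth_col
from methrev.tiling import (TilingParams, filter_blacklist, filter_depth,
                            make_tiles, normalize_coverage, promoter_interval,
                            restrict_to_promoters)

SAMPLES = ["s1", "s2", "s3", "s4"]


def table_from_sites(rows):
    """rows: list of (pos, [(meth, cov) per sample])."""
    data = {"chrom": ["chr1"] * len(rows), "pos": [r[0] for r in rows]}
    for j, s in enumerate(SAMPLES):
        data[meth_col(s)] = [r[1][j][0] for r in rows]
        data[cov_col(s)] = [r[1][j][1] for r in rows]
    return pd.DataFrame(data)


class TestDepthFilter:
    def test_site_below_depth_in_one_sample_dropped(self):
        t = table_from_sites([(100, [(5, 12), (4, 9), (10, 30), (7, 15)])])
        assert filter_depth(t, SAMPLES, 10).empty

    def test_boundary_is_inclusive(self):
        t = table_from_sites([(100, [(5, 10)] * 4)])
        assert len(filter_depth(t, SAMPLES, 10)) == 1

    def test_zero_min_depth_is_identity(self):
        t = table_from_sites([(100, [(0, 0)] * 4), (200, [(1, 2)] * 4)])
        pd.testing.assert_frame_equal(filter_depth(t, SAMPLES, 0), t)

    def test_monotone_in_min_depth(self):
        rng = np.random.default_rng(3)
        rows = [(int(p), [(0, int(c)) for c in rng.integers(0, 40, 4)])
                for p in range(0, 500, 10)]
        t = table_from_sites(rows)
        sizes = [len(filter_depth(t, SAMPLES, d)) for d in range(0, 40, 5)]
        assert sizes == sorted(sizes, reverse=True)


class TestBlacklist:
    def test_contained_site_removed_half_open_boundary_kept(self):
        t = table_from_sites([(100, [(1, 10)] * 4), (150, [(1, 10)] * 4)])
        out = filter_blacklist(t, [GenomicInterval("chr1", 50, 150)])
        assert out["pos"].tolist() == [150]

    def test_empty_blacklist_is_identity(self):
        t = table_from_sites([(100, [(1, 10)] * 4)])
        pd.testing.assert_frame_equal(filter_blacklist(t, []), t)

    def test_other_chromosome_untouched(self):
        t = table_from_sites([(100, [(1, 10)] * 4)])
        out = filter_blacklist(t, [GenomicInterval("chr2", 0, 1000)])
        assert len(out) == 1


class TestNormalizeCoverage:
    def test_median_scaling_factors(self):
        rows = [(p, [(0, 20), (0, 40), (0, 20), (0, 40)])
                for p in range(0, 90, 10)]
        t = table_from_sites(rows)
        _, factors = normalize_coverage(t, SAMPLES)
        assert factors["s1"] == pytest.approx(1.5)
        assert factors["s2"] == pytest.approx(0.75)

    def test_equal_medians_leave_counts_unchanged(self):
        t = table_from_sites([(0, [(3, 10)] * 4), (10, [(5, 20)] * 4)])
        out, factors = normalize_coverage(t, SAMPLES)
        assert all(f == 1.0 for f in factors.values())
        pd.testing.assert_frame_equal(out, t)

    def test_proportion_preserved_under_scaling(self):
        # sample s1 median 10, others 15 -> factor for s1 is 1.5
        t = table_from_sites([(0, [(8, 10), (8, 15), (8, 15), (8, 15)])])
        out, factors = normalize_coverage(t, SAMPLES)
        assert factors["s1"] == pytest.approx(1.5)
        assert out.loc[0, cov_col("s1")] == 15
        assert out.loc[0, meth_col("s1")] == 12

    def test_zero_median_is_hard_error(self):
        t = table_from_sites([(0, [(0, 0), (1, 10), (1, 10), (1, 10)])])
        with pytest.raises(ValueError, match="median"):
            normalize_coverage(t, SAMPLES)


class TestMakeTiles:
    def test_interior_cpg_belongs_to_two_windows(self):
        t = table_from_sites([(300, [(1, 10)] * 4)])
        tiles = make_tiles(t, SAMPLES, TilingParams())
        assert tiles["start"].tolist() == [125, 250]

    def test_chromosome_start_edge_single_window(self):
        t = table_from_sites([(100, [(1, 10)] * 4)])
        tiles = make_tiles(t, SAMPLES, TilingParams())
        assert tiles["start"].tolist() == [0]

    def test_counts_summed_within_tile(self):
        t = table_from_sites([(10, [(8, 10)] * 4), (20, [(2, 10)] * 4)])
        tiles = make_tiles(t, SAMPLES, TilingParams())
        row = tiles.loc[tiles["start"] == 0].iloc[0]
        assert row[meth_col("s1")] == 10 and row[cov_col("s1")] == 20
        assert row["n_cpgs"] == 2

    def test_non_overlapping_steps_partition_cpgs(self):
        rng = np.random.default_rng(0)
        rows = [(int(p), [(1, 10)] * 4)
                for p in sorted(rng.choice(5000, 200, replace=False))]
        t = table_from_sites(rows)
        tiles = make_tiles(t, SAMPLES, TilingParams(tile_size=250, step_size=250))
        assert tiles["n_cpgs"].sum() == len(t)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 2000), min_size=1, max_size=40))
    def test_tile_totals_conserve_member_cpg_counts(self, positions):
        rows = [(p, [(1, 3)] * 4) for p in sorted(positions)]
        t = table_from_sites(rows)
        params = TilingParams()
        tiles = make_tiles(t, SAMPLES, params)
        for _, tile in tiles.iterrows():
            members = t[(t["pos"] >= tile["start"]) & (t["pos"] < tile["end"])]
            assert tile[cov_col("s1")] == members[cov_col("s1")].sum()
            assert tile["n_cpgs"] == len(members)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TilingParams(tile_size=100, step_size=200)


class TestPromoterRestriction:
    GENES = [GenomicInterval("chr1", 10000, 11000, "GA", "+")]

    def _tiles(self, spans):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [s for s, _ in spans],
            "end": [e for _, e in spans],
            "n_cpgs": 1,
            **{c: 1 for s in SAMPLES for c in (meth_col(s), cov_col(s))}})

    def test_tile_overlapping_promoter_retained(self):
        out = restrict_to_promoters(self._tiles([(7900, 8150)]), self.GENES,
                                    TilingParams())
        assert len(out) == 1 and out.loc[0, "genes"] == "GA"

    def test_tile_past_downstream_limit_dropped(self):
        out = restrict_to_promoters(self._tiles([(10250, 10500)]), self.GENES,
                                    TilingParams())
        assert out.empty

    def test_minus_strand_promoter_is_mirrored(self):
        gene = [GenomicInterval("chr1", 9001, 10001, "GB", "-")]  # TSS 10000
        kept = restrict_to_promoters(self._tiles([(11800, 12050)]), gene,
                                     TilingParams())
        dropped = restrict_to_promoters(self._tiles([(7900, 8150)]), gene,
                                        TilingParams())
        assert len(kept) == 1 and dropped.empty

    def test_tile_overlapping_two_promoters_carries_both(self):
        genes = [GenomicInterval("chr1", 10000, 11000, "GA", "+"),
                 GenomicInterval("chr1", 7000, 9400, "GB", "-")]  # TSS 9399
        out = restrict_to_promoters(self._tiles([(9300, 9550)]), genes,
                                    TilingParams())
        assert out.loc[0, "genes"] == "GA,GB"

    def test_gene_without_strand_is_hard_error(self):
        genes = [GenomicInterval("chr1", 10000, 11000, "GA", None)]
        with pytest.raises(ValueError, match="strand"):
            restrict_to_promoters(self._tiles([(9000, 9250)]), genes,
                                  TilingParams())

    def test_promoter_window_geometry(self):
        assert promoter_interval(10000, "+", TilingParams()) == (8000, 10201)
        assert promoter_interval(10000, "-", TilingParams()) == (9800, 12001)
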