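import statistics

import pytest

from rangealign.alignment import (
    AlignmentError,
    QuadrantLabel,
    QuadrantThresholds,
    alignment,
    classify_quadrant,
    cohort_thresholds,
    data_quality_summary,
    summarize_alignment,
)
from rangealign.grid import GridError
from rangealign.pairing import Dataset, SpeciesRecord
from rangealign.polygons import rasterize_polygons
from rangealign.rasters import PresenceRaster, threshold_presence
from rangealign.synthetic import SimConfig, gen_cohort


def eq_cells(grid, cols, row_offset=0):
    r = grid.n_rows // 2 - 1 + row_offset
    return frozenset((r, c) for c in cols)


def pres(grid, cols, sid="s", row_offset=0):
    return PresenceRaster(sid, grid, eq_cells(grid, cols, row_offset))


class TestAlignment:
    def test_identical_rasters(self, grid):
        a = pres(grid, range(10))
        res = alignment(a, pres(grid, range(10), "t"))
        assert (res.alpha_dist, res.alpha_area) == (100.0, 100.0)
        assert res.larger_dataset == "tie"

    def test_disjoint_equal_area(self, grid):
        res = alignment(pres(grid, range(10)), pres(grid, range(20, 30), "t"))
        assert res.alpha_dist == 0.0
        assert res.alpha_area == 100.0

    def test_equatorial_10_20_5(self, grid):
        a = pres(grid, range(10))          # 10 cells
        b = pres(grid, range(5, 25), "t")  # 20 cells, overlap 5
        res = alignment(a, b)
        assert res.alpha_area == pytest.approx(50.0)
        assert res.alpha_dist == pytest.approx(25.0)
        assert res.overlap_pct_of_smaller == pytest.approx(50.0)
        assert res.larger_dataset == "b"

    def test_both_empty_is_error(self, grid):
        e = PresenceRaster("e", grid, frozenset())
        with pytest.raises(AlignmentError):
            alignment(e, e)

    def test_mixed_grids_rejected(self, grid, coarse_grid):
        with pytest.raises(GridError):
            alignment(pres(grid, [0]), pres(coarse_grid, [0], "t"))

    def test_symmetric_up_to_larger_flag(self, grid):
        a, b = pres(grid, range(10)), pres(grid, range(5, 25), "t")
        fwd, rev = alignment(a, b), alignment(b, a)
        assert fwd.alpha_dist == rev.alpha_dist
        assert fwd.alpha_area == rev.alpha_area
        assert {fwd.larger_dataset, rev.larger_dataset} == {"a", "b"}

    def test_metric_order_on_synthetic_cohort(self):
        cfg = SimConfig(seed=5, n_species=40)
        for pair in gen_cohort(cfg):
            pa = rasterize_polygons(pair.polygons, cfg.grid)
            pb = threshold_presence(pair.probability, 0.5)
            res = alignment(pa, pb)
            assert 0.0 <= res.alpha_dist <= res.alpha_area <= 100.0

    def test_shrinking_larger_raises_alpha_dist(self, grid):
        small = pres(grid, range(10))
        prev = None
        for width in (40, 30, 20, 10):  # larger range shrinks toward overlap
            large = pres(grid, range(width), "t")
            val = alignment(small, large).alpha_dist
            if prev is not None:
                assert val >= prev
            prev = val


class TestQuadrants:
    TH = QuadrantThresholds(dist_mean=63.1, area_mean=54.8)

    def fake(self, d, a):
        from rangealign.alignment import AlignmentResult

        return AlignmentResult("x", a, 100.0, d, d, a, "a")

    def test_boundary_goes_upper_right(self):
        res = self.fake(self.TH.dist_mean, self.TH.area_mean)
        assert classify_quadrant(res, self.TH) is QuadrantLabel.WELL_ALIGNED

    def test_zero_dist_full_area(self):
        assert classify_quadrant(self.fake(0.0, 100.0), self.TH) is QuadrantLabel.AREA_ALIGNED

    def test_full_alignment(self):
        assert classify_quadrant(self.fake(100.0, 100.0), self.TH) is QuadrantLabel.WELL_ALIGNED

    def test_low_both(self):
        assert classify_quadrant(self.fake(1.0, 2.0), self.TH) is QuadrantLabel.POORLY_ALIGNED


class TestSummaries:
    def test_single_species_means(self, grid):
        a = pres(grid, range(10))
        b = pres(grid, range(5, 25), "t")
        res = [alignment(a, b)]
        out = summarize_alignment(res)
        row = out["overall"].iloc[0]
        assert row["mean_alpha_dist"] == pytest.approx(25.0)
        assert row["mean_alpha_area"] == pytest.approx(50.0)

    def test_quadrant_percentages_partition(self):
        cfg = SimConfig(seed=7, n_species=60)
        results = []
        for pair in gen_cohort(cfg):
            pa = rasterize_polygons(pair.polygons, cfg.grid)
            pb = threshold_presence(pair.probability, 0.5)
            results.append(alignment(pa, pb))
        out = summarize_alignment(results)
        assert out["quadrants"]["pct"].sum() == pytest.approx(100.0)
        assert out["quadrants"]["n"].sum() == len(results)

    def test_cohort_mean_recovery(self):
        # planted mean overlap 0.6 of the larger range
        cfg = SimConfig(
            seed=13, n_species=300, overlap_fraction=0.6, size_ratio=0.85,
            cohort_spread=0.1,
        )
        results = []
        for pair in gen_cohort(cfg):
            pa = rasterize_polygons(pair.polygons, cfg.grid)
            pb = threshold_presence(pair.probability, 0.5)
            results.append(alignment(pa, pb))
        th = cohort_thresholds(results)
        assert th.dist_mean == pytest.approx(60.0, abs=3.0)
        assert th.area_mean == pytest.approx(85.0, abs=3.0)


class TestDataQuality:
    def make_results(self, grid):
        # two species forced into poorly_aligned, two well_aligned
        out = []
        for i, (cols_a, cols_b) in enumerate(
            [
                (range(10), range(10)),        # perfect -> well
                (range(10), range(9, 19)),     # high -> well
                (range(10), range(30, 70)),    # poor
                (range(10), range(80, 130)),   # poor
            ]
        ):
            a = pres(grid, cols_a, f"sp{i}")
            b = pres(grid, cols_b, f"sp{i}")
            out.append(alignment(a, b, f"sp{i}"))
        return out

    def test_planted_low_occurcells_in_poor_quadrant(self, grid):
        results = self.make_results(grid)
        th = QuadrantThresholds(50.0, 50.0)
        records = {}
        for i in range(4):
            records[f"sp{i}"] = SpeciesRecord(
                dataset=Dataset.MODEL_RASTER,
                species_id=f"sp{i}",
                binomial=f"G s{i}",
                occurcells=5 if i >= 2 else 100,
                occurrence_records=30 if i >= 2 else 250,
            )
        table = data_quality_summary(results, records, th).set_index("group")
        assert (
            table.loc["poorly_aligned", "median_occurcells"]
            < table.loc["other", "median_occurcells"]
        )

    def test_all_metadata_missing(self, grid):
        results = self.make_results(grid)
        th = QuadrantThresholds(50.0, 50.0)
        with pytest.warns(UserWarning):
            table = data_quality_summary(results, {}, th).set_index("group")
        assert table["n_excluded"].sum() == 4
        assert table["median_occurcells"].isna().all()

    def test_median_is_middle_order_statistic(self):
        assert statistics.median([3.0, 10.0, 41.0]) == 10.0
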