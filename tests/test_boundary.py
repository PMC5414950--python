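import pytest

from helpers import exhaustive_edge
from rangealign.boundary import (
    BoundaryMeridian,
    LatBand,
    boundary_coincidence,
    crop_band,
    extrapolation_rate,
    range_edge,
)
from rangealign.rasters import PresenceRaster
from rangealign.synthetic import SimConfig, gen_truncated_ranges

DOMAIN = (20.0, -140.0)  # Indo-Pacific, traversed eastward across 180


def pres(grid, cells, sid="s"):
    return PresenceRaster(sid, grid, frozenset(cells))


class TestCropBand:
    def test_global_band_is_identity(self, grid):
        p = pres(grid, {(100, 10), (300, 700)})
        assert crop_band(p, LatBand(-90, 90)).occupied == p.occupied

    def test_disjoint_band_empties(self, grid):
        p = pres(grid, {(0, 10)})  # lat (89.5, 90]
        assert not crop_band(p, LatBand(-25, 20)).occupied

    def test_narrow_band_rejected(self, grid):
        with pytest.raises(ValueError, match="narrower"):
            crop_band(pres(grid, {(0, 0)}), LatBand(0.0, 0.3))

    def test_straddling_range_keeps_analytic_rows(self, grid):
        # rows 139..141 have lat spans (20,20.5], (19.5,20], (19,19.5]
        p = pres(grid, {(r, 500) for r in range(135, 146)})
        kept = crop_band(p, LatBand(-25.0, 20.0)).occupied
        assert {r for r, _ in kept} == set(range(140, 146))

    def test_idempotent_and_commutes_with_intersection(self, grid):
        band = LatBand(-25.0, 20.0)
        a = pres(grid, {(r, c) for r in range(130, 150) for c in range(5)})
        b = pres(grid, {(r, c) for r in range(135, 160) for c in range(3)})
        ca = crop_band(a, band)
        assert crop_band(ca, band).occupied == ca.occupied
        inter_then_crop = crop_band(
            pres(grid, a.occupied & b.occupied), band
        ).occupied
        crop_then_inter = ca.occupied & crop_band(b, band).occupied
        assert inter_then_crop == crop_then_inter


class TestRangeEdge:
    def test_single_cell_east_edge(self, grid):
        p = pres(grid, {grid.point_to_cell(170.25, 0.25)})
        assert range_edge(p, "east", DOMAIN) == pytest.approx(170.5)

    def test_negative_longitude_edge(self, grid):
        # eastmost cell spans [-175.5, -175.0): its eastern edge is 175 W
        cells = {grid.point_to_cell(-175.75, 0.25), grid.point_to_cell(-175.25, 0.25)}
        p = pres(grid, cells)
        assert range_edge(p, "east", DOMAIN) == pytest.approx(-175.0)

    def test_west_edge(self, grid):
        p = pres(grid, {grid.point_to_cell(100.25, 0.0), grid.point_to_cell(120.25, 0.0)})
        assert range_edge(p, "west", DOMAIN) == pytest.approx(100.0)

    def test_matches_exhaustive_scan(self, grid, rng):
        for _ in range(25):
            cells = set()
            for _ in range(int(rng.integers(1, 40))):
                # longitudes within the domain only
                lon = float(rng.uniform(21.0, 219.0))  # east of 20E, wraps past 180
                lon = ((lon + 180.0) % 360.0) - 180.0
                lat = float(rng.uniform(-24.0, 19.0))
                cells.add(grid.point_to_cell(lon, lat))
            p = pres(grid, cells)
            for side in ("east", "west"):
                assert range_edge(p, side, DOMAIN) == pytest.approx(
                    exhaustive_edge(cells, grid, side, DOMAIN)
                )

    def test_empty_after_crop_rejected(self, grid):
        with pytest.raises(ValueError):
            range_edge(pres(grid, set()), "east", DOMAIN)

    def test_cells_outside_domain_ignored(self, grid):
        inside = grid.point_to_cell(100.25, 0.0)
        outside = grid.point_to_cell(-100.25, 0.0)  # Atlantic side
        p = pres(grid, {inside, outside})
        assert range_edge(p, "east", DOMAIN) == pytest.approx(100.5)


class TestBoundaryCoincidence:
    def test_generator_ground_truth_recovered(self):
        cfg = SimConfig(seed=21, n_species=60, truncated_fraction=0.3)
        cohort = gen_truncated_ranges(cfg)
        hits = boundary_coincidence(
            cohort.rasters,
            LatBand(*cohort.band),
            [BoundaryMeridian(cohort.meridian, "71/77")],
            "east",
            cohort.domain,
        )
        assert {h.species_id for h in hits} == set(cohort.truncated_ids)
        assert all(h.cells_at_edge >= 1 for h in hits)

    @pytest.mark.parametrize("fraction,expected", [(0.0, 0), (1.0, 30)])
    def test_all_or_none(self, fraction, expected):
        cfg = SimConfig(seed=22, n_species=30, truncated_fraction=fraction)
        cohort = gen_truncated_ranges(cfg)
        hits = boundary_coincidence(
            cohort.rasters,
            LatBand(*cohort.band),
            [BoundaryMeridian(cohort.meridian)],
            "east",
            cohort.domain,
        )
        assert len(hits) == expected

    def test_one_cell_short_not_flagged(self, grid):
        # eastern edge at -175.5, one cell short of the 175 W meridian
        cells = {(200, c) for c in range(0, 9)}
        hits = boundary_coincidence(
            [pres(grid, cells)], LatBand(-25, 20), [BoundaryMeridian(-175.0)],
            "east", DOMAIN,
        )
        assert hits == []

    def test_spanning_across_not_flagged(self, grid):
        cells = {(200, c) for c in range(0, 12)}  # crosses past -175
        hits = boundary_coincidence(
            [pres(grid, cells)], LatBand(-25, 20), [BoundaryMeridian(-175.0)],
            "east", DOMAIN,
        )
        assert hits == []

    def test_invariant_under_adding_westward_cells(self, grid):
        cells = {(200, c) for c in range(0, 10)}  # edge exactly at -175
        base = boundary_coincidence(
            [pres(grid, cells)], LatBand(-25, 20), [BoundaryMeridian(-175.0)],
            "east", DOMAIN,
        )
        widened = boundary_coincidence(
            [pres(grid, cells | {(200, c) for c in range(660, 720)})],
            LatBand(-25, 20), [BoundaryMeridian(-175.0)], "east", DOMAIN,
        )
        assert [h.species_id for h in base] == [h.species_id for h in widened]

    def test_off_grid_meridian_rejected(self, grid):
        from rangealign.grid import GridError

        with pytest.raises(GridError):
            boundary_coincidence(
                [pres(grid, {(200, 0)})], LatBand(-25, 20),
                [BoundaryMeridian(-175.3)], "east", DOMAIN,
            )


class TestExtrapolationRate:
    def test_division(self):
        assert extrapolation_rate(1_000_000.0, 4) == 250_000.0

    def test_doubling_cells_halves_rate(self):
        assert extrapolation_rate(5.4e6, 232) == extrapolation_rate(5.4e6, 116) / 2

    def test_zero_cells_undefined(self):
        with pytest.raises(ValueError):
            extrapolation_rate(1000.0, 0)

    def test_planted_rate_difference_recovered(self, grid, rng):
        # flagged species: large ranges from few occurrence cells
        flagged = [(pres(grid, {(180, c) for c in range(40)}, f"f{i}"), 4) for i in range(10)]
        others = [(pres(grid, {(180, c) for c in range(40)}, f"o{i}"), 40) for i in range(10)]
        import statistics

        from rangealign.rasters import range_area_km2

        mean_flagged = statistics.fmean(
            extrapolation_rate(range_area_km2(p), n) for p, n in flagged
        )
        mean_other = statistics.fmean(
            extrapolation_rate(range_area_km2(p), n) for p, n in others
        )
        assert mean_flagged == pytest.approx(10 * mean_other)
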