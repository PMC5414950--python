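import math

import numpy as np
import pytest

from rangealign.alignment import alignment, cohort_thresholds
from rangealign.habitat import (
    BathymetryRaster,
    aggregate_bathymetry_min,
    build_depth_mask,
    clip_presence,
    eliminated_fraction,
    reclassification_table,
)
from rangealign.rasters import PresenceRaster
from rangealign.synthetic import SimConfig, gen_bathymetry, gen_drowned_pairs


def uniform_bathy(grid, depth, rows=range(100, 110), cols=range(200, 220)):
    return BathymetryRaster(grid, {(r, c): depth for r in rows for c in cols})


class TestDepthMask:
    def test_uniform_shallow_all_allowed(self, grid):
        bathy = uniform_bathy(grid, 100.0)
        mask = build_depth_mask(bathy, 200.0)
        assert mask.allowed == frozenset(bathy.depth_m)

    def test_uniform_deep_empty_with_warning(self, grid):
        bathy = uniform_bathy(grid, 4000.0)
        with pytest.warns(UserWarning, match="empty"):
            mask = build_depth_mask(bathy, 200.0)
        assert not mask.allowed

    def test_strictly_shallower_than_limit(self, grid):
        bathy = BathymetryRaster(grid, {(0, 0): 199.99, (0, 1): 200.0})
        mask = build_depth_mask(bathy, 200.0)
        assert mask.allowed == frozenset({(0, 0)})

    def test_nonpositive_limit_rejected(self, grid):
        with pytest.raises(ValueError):
            build_depth_mask(uniform_bathy(grid, 10.0), 0.0)

    def test_shelf_mask_matches_analytic_isobath(self):
        cfg = SimConfig(seed=2)
        bathy, truth = gen_bathymetry(cfg)
        mask = build_depth_mask(bathy, 200.0)
        # 20 m/deg slope from -20E puts the 200 m isobath at -10E
        assert truth["isobath_lon_200m"] == pytest.approx(-10.0)
        res = cfg.grid.resolution_deg
        col_limit = math.ceil((truth["isobath_lon_200m"] + 180.0) / res)
        expected = frozenset(
            cell for cell in bathy.depth_m if cell[1] < col_limit
        )
        assert mask.allowed == expected

    def test_min_aggregation_keeps_shallow_sliver(self, grid):
        fine = np.full((5, 5), 300.0)
        fine[0, 0] = 150.0  # one shallow fine cell in the block
        bathy = aggregate_bathymetry_min(fine, 0.1, grid, origin=(40, 40))
        assert bathy.depth_m[(40, 40)] == 150.0
        assert (40, 40) in build_depth_mask(bathy, 200.0).allowed

    def test_all_nan_block_absent(self, grid):
        fine = np.full((10, 10), np.nan)
        fine[6, 6] = 10.0
        bathy = aggregate_bathymetry_min(fine, 0.25, grid, origin=(0, 0))
        assert set(bathy.depth_m) == {(3, 3)}


class TestClip:
    def test_superset_mask_is_identity(self, grid):
        pres = PresenceRaster("s", grid, frozenset({(100, 200), (100, 201)}))
        mask = build_depth_mask(uniform_bathy(grid, 50.0), 200.0)
        assert clip_presence(pres, mask).occupied == pres.occupied

    def test_empty_mask_empties_range(self, grid):
        pres = PresenceRaster("s", grid, frozenset({(100, 200)}))
        with pytest.warns(UserWarning):
            mask = build_depth_mask(uniform_bathy(grid, 4000.0), 200.0)
        assert not clip_presence(pres, mask).occupied

    def test_clip_never_grows(self, grid, rng):
        mask = build_depth_mask(uniform_bathy(grid, 100.0), 200.0)
        for _ in range(10):
            cells = frozenset(
                (int(rng.integers(95, 115)), int(rng.integers(195, 225)))
                for _ in range(30)
            )
            pres = PresenceRaster("s", grid, cells)
            clipped = clip_presence(pres, mask)
            assert clipped.occupied <= pres.occupied


class TestEliminatedFraction:
    def test_no_change_is_zero(self, grid):
        pres = PresenceRaster("s", grid, frozenset({(1, 1)}))
        assert eliminated_fraction(pres, pres) == 0.0

    def test_total_loss_is_hundred(self, grid):
        pres = PresenceRaster("s", grid, frozenset({(1, 1)}))
        empty = PresenceRaster("s", grid, frozenset())
        assert eliminated_fraction(pres, empty) == 100.0

    def test_empty_before_rejected(self, grid):
        empty = PresenceRaster("s", grid, frozenset())
        with pytest.raises(ValueError):
            eliminated_fraction(empty, empty)

    def test_non_subset_rejected(self, grid):
        a = PresenceRaster("s", grid, frozenset({(1, 1)}))
        b = PresenceRaster("s", grid, frozenset({(2, 2)}))
        with pytest.raises(ValueError):
            eliminated_fraction(a, b)

    def test_drowned_fraction_recovery(self):
        cfg = SimConfig(seed=9, n_species=40)
        pairs, bathy = gen_drowned_pairs(cfg, max_depth_m=200.0)
        mask = build_depth_mask(bathy, 200.0)
        errs = []
        for pair in pairs:
            clipped = clip_presence(pair.expert, mask)
            got = eliminated_fraction(pair.expert, clipped)
            errs.append(got - 100.0 * pair.drowned_fraction_true)
        assert np.abs(errs).max() < 1e-9  # same-row construction is exact
        mean_elim = np.mean(
            [100.0 * p.drowned_fraction_true for p in pairs]
        )
        assert mean_elim == pytest.approx(100 * cfg.drowned_fraction, abs=5.0)


class TestReclassification:
    def coral_results(self, cfg):
        pairs, bathy = gen_drowned_pairs(cfg, max_depth_m=200.0)
        mask = build_depth_mask(bathy, 200.0)
        before, after = [], []
        for p in pairs:
            before.append(alignment(p.expert, p.model, p.expert.species_id))
            after.append(
                alignment(clip_presence(p.expert, mask), p.model, p.expert.species_id)
            )
        return before, after

    def test_identity_without_clipping(self):
        cfg = SimConfig(seed=4, n_species=20)
        before, _ = self.coral_results(cfg)
        th = cohort_thresholds(before)
        trans, membership = reclassification_table(before, before, th)
        assert np.trace(trans.values) == len(before)
        assert membership["pct_before"].tolist() == membership["pct_after"].tolist()

    def test_row_sums_conserve_before_counts(self):
        cfg = SimConfig(seed=4, n_species=20)
        before, after = self.coral_results(cfg)
        th = cohort_thresholds(before)
        trans, membership = reclassification_table(before, after, th)
        assert trans.values.sum() == len(before)
        assert membership["pct_before"].sum() == pytest.approx(100.0)
        assert membership["pct_after"].sum() == pytest.approx(100.0)

    def test_clipping_commission_error_flows_to_well_aligned(self):
        cfg = SimConfig(seed=4, n_species=30)
        before, after = self.coral_results(cfg)
        th = cohort_thresholds(before)
        trans, membership = reclassification_table(before, after, th)
        well = "well_aligned"
        assert (
            membership.set_index("quadrant").loc[well, "pct_after"]
            > membership.set_index("quadrant").loc[well, "pct_before"]
        )
        # movement out of any quadrant lands in the well-aligned column only
        for q in trans.index:
            if q == well:
                continue
            moved = trans.loc[q].drop([q, well]).sum()
            assert moved == 0

    def test_alpha_dist_nondecreasing_when_only_unsuitable_removed(self):
        cfg = SimConfig(seed=4, n_species=25)
        before, after = self.coral_results(cfg)
        for rb, ra in zip(before, after):
            assert ra.alpha_dist >= rb.alpha_dist - 1e-9

    def test_species_set_mismatch_rejected(self):
        cfg = SimConfig(seed=4, n_species=10)
        before, after = self.coral_results(cfg)
        th = cohort_thresholds(before)
        with pytest.raises(ValueError):
            reclassification_table(before, after[:-1], th)
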