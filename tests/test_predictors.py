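"""Terrain indices, landmass shape, locality statistics and the
standardization transform, each checked against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paleodrivers as pdv
from paleodrivers import predictors as pred
from paleodrivers.containers import ValidationError


def brute_force_tri(elev: np.ndarray, mask: np.ndarray) -> float:
    """Independent double-loop Riley TRI over all evaluable land cells."""
    nrows, ncols = elev.shape
    vals = []
    for r in range(nrows):
        for c in range(ncols):
            if not mask[r, c]:
                continue
            sq, seen = 0.0, False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc]:
                        sq += (elev[r, c] - elev[rr, cc]) ** 2
                        seen = True
            if seen:
                vals.append(math.sqrt(sq))
    return float(np.mean(vals))


class TestTRI:
    def test_flat_grid_is_zero(self, square_grid):
        assert pred.compute_tri(square_grid) == 0.0

    def test_single_raised_neighbour_hand_value(self):
        elev = np.full((3, 3), 100.0)
        elev[1, 2] = 104.0  # one edge neighbour of the centre
        g = pdv.ElevationGrid(elev, np.ones((3, 3), bool), cellsize=1.0)
        tri = pred._tri_per_cell(g)
        assert tri[1, 1] == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        elev = rng.uniform(0, 500, (20, 20))
        mask = rng.uniform(size=(20, 20)) > 0.2
        mask[0, 0] = True
        g = pdv.ElevationGrid(np.where(mask, elev, np.nan), mask, cellsize=1.0)
        assert pred.compute_tri(g) == pytest.approx(
            brute_force_tri(elev, mask), rel=1e-12
        )


class TestLandmassShape:
    def test_square_area_exact_perimeter_close(self, square_grid):
        P, A = pred.extract_landmass_shape(square_grid)
        assert A == 1600.0
        assert P == pytest.approx(160.0, rel=0.02)

    def test_disc_shoreline_development_near_one(self):
        n = 101
        yy, xx = np.mgrid[0:n, 0:n]
        mask = (xx - 50) ** 2 + (yy - 50) ** 2 <= 30**2
        g = pdv.ElevationGrid(np.where(mask, 10.0, np.nan), mask, 1.0)
        P, A = pred.extract_landmass_shape(g)
        assert pred.shoreline_development(P, A) == pytest.approx(1.0, abs=0.03)

    def test_two_disjoint_squares_double_both(self, square_grid):
        mask = np.zeros((40, 100), bool)
        mask[:, :40] = True
        mask[:, 60:] = True
        g2 = pdv.ElevationGrid(np.where(mask, 100.0, np.nan), mask, 1.0)
        P1, A1 = pred.extract_landmass_shape(square_grid)
        P2, A2 = pred.extract_landmass_shape(g2)
        assert A2 == 2 * A1
        assert P2 == pytest.approx(2 * P1, rel=0.01)

    def test_scale_invariance_of_shoreline_development(self):
        # doubling all linear dimensions leaves D unchanged within raster error
        def disc_D(r, n):
            yy, xx = np.mgrid[0:n, 0:n]
            m = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= r**2
            g = pdv.ElevationGrid(np.where(m, 1.0, np.nan), m, 1.0)
            return pred.shoreline_development(*pred.extract_landmass_shape(g))

        assert disc_D(20, 61) == pytest.approx(disc_D(40, 121), abs=0.02)

    def test_empty_mask_raises(self):
        g = pdv.ElevationGrid(
            np.full((5, 5), np.nan), np.zeros((5, 5), bool), 1.0
        )
        with pytest.raises(ValidationError):
            pred.extract_landmass_shape(g)


class TestShorelineAndTCI:
    def test_circle_gives_one(self):
        A = 10.0
        P = 2 * math.sqrt(math.pi * A)
        assert pred.shoreline_development(P, A) == pytest.approx(1.0)

    def test_unit_square_closed_form(self):
        assert pred.shoreline_development(4.0, 1.0) == pytest.approx(
            2 / math.sqrt(math.pi)
        )

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValidationError):
            pred.shoreline_development(100.0, 0.0)
        with pytest.raises(ValidationError):
            pred.compute_tci(0.0, 1.0, 5.0)

    def test_tci_circle_equals_tri(self):
        A = 25.0
        P = 2 * math.sqrt(math.pi * A)
        assert pred.compute_tci(P, A, 50.0) == pytest.approx(50.0)

    def test_tci_unit_square(self):
        assert pred.compute_tci(4.0, 1.0, 10.0) == pytest.approx(
            10 * 2 / math.sqrt(math.pi)
        )

    def test_flat_terrain_gives_zero(self):
        assert pred.compute_tci(4.0, 1.0, 0.0) == 0.0


def _locs(rows):
    return pdv.LocalityTable(pd.DataFrame(
        rows, columns=["locality_id", "lon", "lat", "age", "basin_id"]
    ))


class TestLocalityStats:
    def test_coincident_points_distance_zero(self):
        t = _locs([("a", 5.0, 5.0, 0.5, "b"), ("b", 5.0, 5.0, 0.5, "b")])
        assert pred.mean_pairwise_distance(t, (0, 1)) == 0.0

    def test_quarter_great_circle(self):
        t = _locs([("a", 0.0, 0.0, 0.5, "b"), ("b", 90.0, 0.0, 0.5, "b")])
        assert pred.mean_pairwise_distance(t, (0, 1)) == pytest.approx(
            math.pi / 2 * 6371.0, rel=1e-6
        )

    def test_three_points_brute_force(self):
        pts = [(0.0, 0.0), (10.0, 5.0), (-3.0, 40.0)]
        t = _locs([(f"l{i}", lon, lat, 0.5, "b")
                   for i, (lon, lat) in enumerate(pts)])
        expected = np.mean([
            pred.haversine_km(*np.array(pts[i]), *np.array(pts[j]))
            for i in range(3) for j in range(i + 1, 3)
        ])
        assert pred.mean_pairwise_distance(t, (0, 1)) == pytest.approx(expected)

    def test_longitude_shift_invariance(self):
        rng = np.random.default_rng(0)
        pts = [(float(rng.uniform(-60, 60)), float(rng.uniform(-50, 50)))
               for _ in range(6)]
        t1 = _locs([(f"l{i}", lon, lat, 0.5, "b")
                    for i, (lon, lat) in enumerate(pts)])
        t2 = _locs([(f"l{i}", lon + 25.0, lat, 0.5, "b")
                    for i, (lon, lat) in enumerate(pts)])
        assert pred.mean_pairwise_distance(t1, (0, 1)) == pytest.approx(
            pred.mean_pairwise_distance(t2, (0, 1))
        )

    def test_single_locality_gives_nan_not_error(self):
        t = _locs([("a", 0.0, 0.0, 0.5, "b")])
        assert np.isnan(pred.mean_pairwise_distance(t, (0, 1)))

    def test_basin_stats_counts_each_basin_once(self):
        t = _locs(
            [(f"l{i}", 0.0, 0.0, 0.5, "b1") for i in range(2)]
            + [("l9", 0.0, 0.0, 0.5, "b2")]
        )
        n, size = pred.basin_stats(t, {"b1": 100.0, "b2": 300.0}, (0, 1))
        assert (n, size) == (2, 200.0)

    def test_basin_stats_empty_slice(self):
        t = _locs([("a", 0.0, 0.0, 5.5, "b1")])
        n, size = pred.basin_stats(t, {"b1": 1.0}, (0, 1))
        assert n == 0 and np.isnan(size)

    def test_missing_basin_area_names_basin(self):
        t = _locs([("a", 0.0, 0.0, 0.5, "b7")])
        with pytest.raises(ValidationError, match="b7"):
            pred.basin_stats(t, {}, (0, 1))


class TestDiversityTrajectory:
    def test_half_open_convention(self, three_species):
        reps = pdv.ReplicateSet([three_species])
        s = pred.diversity_trajectory(reps, 100.0)
        n = dict(zip(np.round(s.ages, 4), s.raw))
        # species a lives (10, 5): alive at 7, dead at 12 and 3
        assert n[7.0] == 1.0 + 1.0  # a alive, b (8..0) alive too
        assert n[12.0] == 0.0
        assert n[3.0] == 1.0  # only extant b
        assert n[10.0] == 0.0  # a not alive at its own ts; b starts at 8
        assert n[5.0] == 2.0  # a alive at its te

    def test_mean_of_identical_replicates(self, three_species):
        one = pred.diversity_trajectory(pdv.ReplicateSet([three_species]), 50.0)
        two = pred.diversity_trajectory(
            pdv.ReplicateSet([three_species, three_species]), 50.0
        )
        np.testing.assert_allclose(one.raw, two.raw)


class TestElevationAndArea:
    def test_continental_area(self):
        mask = np.zeros((5, 5), bool)
        mask.flat[:10] = True
        g = pdv.ElevationGrid(np.where(mask, 1.0, np.nan), mask, 50.0)
        assert pred.continental_area(g) == 25_000.0
        g_empty = pdv.ElevationGrid(
            np.full((5, 5), np.nan), np.zeros((5, 5), bool), 50.0
        )
        assert pred.continental_area(g_empty) == 0.0

    def test_elevation_range_neighbourhood(self):
        elev = np.full((3, 3), 100.0)
        elev[0, 0] = 104.0
        g = pdv.ElevationGrid(elev, np.ones((3, 3), bool), 1.0)
        assert pred.elevation_range(g, [(1, 1)]) == pytest.approx(4.0)
        assert pred.elevation_range(g, [(2, 2)]) == 0.0


class TestStandardize:
    def test_constant_series_degenerates_to_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            s = pred.standardize_series(
                np.array([0.0, 100.0]), np.array([7.0, 7.0]), 100.0, name="c"
            )
        assert np.all(s.transformed == 0.0)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        s = pred.standardize_series(
            np.arange(0, 101, 10.0), rng.uniform(5, 20, 11), 100.0
        )
        assert abs(s.transformed.mean()) < 1e-9
        assert abs(s.transformed.std() - 1.0) < 1e-9

    def test_linear_interpolation_oracle(self):
        s = pred.standardize_series(
            np.array([0.0, 100.0]), np.array([1.0, 100.0]), 100.0
        )
        i = np.argmin(np.abs(s.ages - 50.0))
        assert s.raw[i] == pytest.approx(50.5)

    def test_positivity_shift_applied_before_log(self):
        s = pred.standardize_series(
            np.array([0.0, 100.0]), np.array([-5.0, 10.0]), 100.0
        )
        assert np.all(np.isfinite(s.transformed))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_idempotent_on_standardized_values(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(1, 50, 11)
        if vals.std() < 1e-6:
            return
        ages = np.arange(0, 101, 10.0)
        s1 = pred.standardize_series(ages, vals, 100.0)
        s2 = pred.standardize_series(
            s1.ages, s1.transformed, 100.0, log_transform=False
        )
        np.testing.assert_allclose(s2.transformed, s1.transformed, atol=1e-9)

    def test_undefined_slices_filled_by_interpolation(self):
        filled = pred.fill_undefined_slices(
            np.array([1.0, np.nan, 3.0, np.nan, np.nan, 9.0])
        )
        np.testing.assert_allclose(filled, [1, 2, 3, 5, 7, 9])


class TestSubsample:
    @pytest.fixture
    def hundred(self):
        rng = np.random.default_rng(0)
        return _locs([
            (f"l{i}", float(rng.uniform(-10, 10)), float(rng.uniform(40, 50)),
             float(rng.uniform(0, 10)), f"b{i % 7}")
            for i in range(100)
        ])

    def test_fraction_one_is_identity(self, hundred):
        assert pred.subsample_localities(hundred, 1.0) is hundred

    def test_uniform_half(self, hundred):
        sub = pred.subsample_localities(hundred, 0.5, seed=1)
        assert len(sub) == 50

    def test_spatial_block_never_splits_basin(self, hundred):
        sub = pred.subsample_localities(
            hundred, 0.5, scheme="spatial-block", seed=2
        )
        kept = set(sub.data["basin_id"])
        counts_all = hundred.data["basin_id"].value_counts()
        counts_sub = sub.data["basin_id"].value_counts()
        for b in kept:
            assert counts_sub[b] == counts_all[b]

    def test_bad_fraction(self, hundred):
        with pytest.raises(ValidationError):
            pred.subsample_localities(hundred, 0.0)
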