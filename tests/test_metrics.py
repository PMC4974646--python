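"""Velocity, MCE and the forward/reverse exposure pipeline."""

import numpy as np
import pytest

from climtraj import (MethodParams, Trajectory, compute_mce,
                      make_flat_gradient, make_peninsula, make_ridge_valley,
                      run_forward, run_reverse, trajectories_to_geojson,
                      velocity_from_distance)

from conftest import oracle_distances


def fixed_trajectory(costs, lengths):
    costs = np.asarray(costs, float)
    lengths = np.asarray(lengths, float)
    return Trajectory(source=(0, 0), destination=(0, len(costs) - 1),
                      path=np.array([(0, i) for i in range(len(costs))]),
                      lengths=lengths, costs=costs,
                      accumulated_cost=float(np.sum(costs * lengths)),
                      med=float(lengths.sum()))


class TestVelocity:
    @pytest.mark.parametrize("dist, time, expected", [
        (0.0, 90.0, 0.0), (90.0, 90.0, 1.0), (100.0, 90.0, 100 / 90),
    ])
    def test_distance_over_time(self, dist, time, expected):
        assert velocity_from_distance(dist, time) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            velocity_from_distance(10.0, 0.0)
        with pytest.raises(ValueError):
            velocity_from_distance(-1.0, 90.0)


class TestComputeMCE:
    def test_all_analogue_path_is_exact_zero(self):
        traj = fixed_trajectory([1, 1, 1, 1], [2.5, 5, 5, 2.5])
        assert compute_mce(traj) == 0.0

    def test_one_cost2_pixel_of_5km_gives_2p5(self):
        traj = fixed_trajectory([1, 2, 1], [2.5, 5.0, 2.5])
        assert compute_mce(traj) == pytest.approx(2.5)

    def test_two_cost2_pixels_or_one_cost3_pixel_gives_5(self):
        two = fixed_trajectory([1, 2, 2, 1], [2.5, 5, 5, 2.5])
        one = fixed_trajectory([1, 3, 1], [2.5, 5.0, 2.5])
        assert compute_mce(two) == pytest.approx(5.0)
        assert compute_mce(one) == pytest.approx(5.0)

    def test_appending_analogue_pixels_changes_med_not_mce(self):
        short = fixed_trajectory([1, 2, 1], [2.5, 5.0, 2.5])
        long = fixed_trajectory([1, 2, 1, 1, 1], [2.5, 5, 5, 5, 2.5])
        assert long.med > short.med
        assert compute_mce(long) == compute_mce(short)

    def test_doubling_penalty_halves_mce_for_fixed_trajectory(self):
        traj = fixed_trajectory([1, 3, 2, 1], [2.5, 5, 5, 2.5])
        m2 = compute_mce(traj, MethodParams(penalty=2.0))
        m4 = compute_mce(traj, MethodParams(penalty=4.0))
        assert m4 == pytest.approx(m2 / 2.0)


class TestRunForward:
    def test_flat_gradient_zero_mce_and_equal_velocities(self, flat_pair):
        cur, fut, truth = flat_pair
        res = run_forward(cur, fut)
        valid = res.valid_mask
        assert valid.any()
        np.testing.assert_array_equal(res.mce[valid], 0.0)
        np.testing.assert_allclose(res.velocity_med[valid],
                                   res.velocity_ed[valid])
        np.testing.assert_allclose(res.ratio[valid], 1.0)

    def test_flat_gradient_recovers_nearest_analogue_displacement(self, flat_pair):
        cur, fut, truth = flat_pair
        res = run_forward(cur, fut)
        r0 = truth["reference_row"]
        expect = truth["nearest_analogue_displacement_km"]
        for c in range(2, 8):
            assert res.med[r0, c] == pytest.approx(expect)
            assert res.ed[r0, c] == pytest.approx(expect)

    def test_exact_displacement_when_gradient_spans_bin_per_pixel(self):
        # gradient 0.5 °C/px: the analogue bin is narrower than one pixel, so
        # the nearest analogue IS the exact match at warming/gradient pixels
        cur, fut, truth = make_flat_gradient(shape=(12, 6), gradient=0.5,
                                             warming=1.0)
        res = run_forward(cur, fut)
        r0 = 6
        assert truth["displacement_pixels"] == 2
        assert res.med[r0, 3] == pytest.approx(2 * 5.0)
        assert res.velocity_med[r0, 3] == pytest.approx(10.0 / 90.0)

    def test_zero_warming_all_velocities_zero(self):
        cur, fut, _ = make_flat_gradient(shape=(15, 6), gradient=0.1,
                                         warming=0.0)
        res = run_forward(cur, fut)
        valid = res.valid_mask
        assert valid.all()
        np.testing.assert_array_equal(res.med[valid], 0.0)
        np.testing.assert_array_equal(res.velocity_med[valid], 0.0)
        np.testing.assert_array_equal(res.mce[valid], 0.0)
        assert (res.dest_row[valid] >= 0).all()

    def test_ridge_pixels_high_mce_short_med(self, ridge_pair):
        cur, fut, truth = ridge_pair
        res = run_forward(cur, fut)
        src = truth["source_rows"]
        mce = res.mce[src, :]
        med = res.med[src, :]
        assert np.isfinite(mce).all()
        np.testing.assert_allclose(mce, truth["expected_mce_at_defaults"])
        assert med.max() < 0.5 * cur.shape[0] * cur.pixel_size * 2

    def test_med_geq_ed_and_velocity_ordering_everywhere(self):
        for cur, fut, _ in (make_flat_gradient(shape=(25, 8)),
                            make_ridge_valley(),
                            make_peninsula()):
            res = run_forward(cur, fut)
            valid = res.valid_mask
            assert (res.med[valid] >= res.ed[valid] - 1e-9).all()
            assert (res.velocity_med[valid] >= res.velocity_ed[valid] - 1e-12).all()
            assert (res.ratio[valid] >= 1.0 - 1e-12).all()
            assert (res.mce[valid] >= 0.0).all()

    def test_no_analogue_sources_flagged_not_fatal(self, ridge_pair):
        cur, fut, truth = ridge_pair
        res = run_forward(cur, fut)
        # valley and destination-ridge sources have no future analogue
        assert res.no_analogue.any()
        assert np.isnan(res.med[res.no_analogue]).all()

    def test_peninsula_tip_routes_south_with_positive_mce(self, peninsula_pair):
        cur, fut, truth = peninsula_pair
        res = run_forward(cur, fut)
        tr = truth["tip_row"]
        c0, c1 = truth["tip_cols"]
        for c in range(c0, c1):
            assert res.mce[tr, c] > 0
            assert res.dest_row[tr, c] > tr, "destination must lie south"
        hr0, hr1 = truth["highland_rows"]
        assert hr0 <= res.dest_row[tr, c0] < hr1

    def test_all_land_control_drops_tip_mce_to_zero(self, peninsula_pair):
        cur, fut, truth = peninsula_pair
        res = run_forward(cur, fut)
        curL, futL, _ = make_peninsula(all_land=True)
        resL = run_forward(curL, futL)
        tr = truth["tip_row"]
        c = sum(truth["tip_cols"]) // 2
        assert res.mce[tr, c] > 0
        assert resL.mce[tr, c] == 0.0
        assert resL.dest_row[tr, c] < tr     # poleward again

    def test_trajectory_accounting_identity(self, ridge_pair):
        cur, fut, _ = ridge_pair
        res = run_forward(cur, fut)
        assert res.trajectories
        for traj in res.trajectories.values():
            lhs = float(np.sum(traj.costs * traj.lengths))
            assert abs(lhs - traj.accumulated_cost) <= 1e-9 * max(traj.med, 1.0)

    def test_dataframe_one_row_per_source(self, ridge_pair):
        cur, fut, _ = ridge_pair
        res = run_forward(cur, fut)
        df = res.to_dataframe()
        assert len(df) == res.source_mask.sum()
        assert {"ed_km", "med_km", "mce", "no_analogue"} <= set(df.columns)


class TestRunReverse:
    def test_zero_warming_reverse_equals_forward_identity(self):
        cur, fut, _ = make_flat_gradient(shape=(12, 6), gradient=0.1,
                                         warming=0.0)
        fwd = run_forward(cur, fut)
        rev = run_reverse(cur, fut)
        for res in (fwd, rev):
            valid = res.valid_mask
            np.testing.assert_array_equal(res.med[valid], 0.0)
        np.testing.assert_array_equal(fwd.med[fwd.valid_mask],
                                      rev.med[rev.valid_mask])

    def test_uniform_warming_reverse_mirrors_forward(self):
        # under a symmetric flat gradient the reverse destination of a pixel
        # is displaced equatorward by the same distance the forward one is
        # displaced poleward
        cur, fut, _ = make_flat_gradient(shape=(30, 6), gradient=0.1,
                                         warming=1.0)
        fwd = run_forward(cur, fut)
        rev = run_reverse(cur, fut)
        r0, c = 15, 3
        dfwd = r0 - fwd.dest_row[r0, c]
        drev = rev.dest_row[r0, c] - r0
        assert dfwd > 0 and drev > 0
        assert dfwd == drev
        assert rev.mce[r0, c] == 0.0

    def test_peninsula_reverse_tip_accessible_via_southern_route(self,
                                                                 peninsula_pair):
        cur, fut, truth = peninsula_pair
        rev = run_reverse(cur, fut)
        tr = truth["tip_row"]
        c = sum(truth["tip_cols"]) // 2
        # the tip's future climate is colonisable only from the south, over land
        assert rev.dest_row[tr, c] > tr
        traj = rev.trajectories[(tr, c)]
        land = cur.land_mask
        assert all(land[r, cc] for r, cc in traj.path)


def test_path_count_raster_counts_traversals(ridge_pair):
    from climtraj import path_count_raster
    cur, fut, truth = ridge_pair
    res = run_forward(cur, fut)
    counts = path_count_raster(res)
    assert counts.sum() == sum(len(t) for t in res.trajectories.values())
    # every source-ridge trajectory crosses the single valley row
    valley_row = int(np.argmax(cur.values[:, 0]))
    assert counts[valley_row, :].sum() >= len(truth["source_rows"])


class TestGeoJSONExport:
    def test_linestring_per_source_with_metrics(self, ridge_pair):
        cur, fut, _ = ridge_pair
        res = run_forward(cur, fut)
        gj = trajectories_to_geojson(res)
        assert gj["type"] == "FeatureCollection"
        assert len(gj["features"]) == len(res.trajectories)
        f = gj["features"][0]
        assert f["geometry"]["type"] == "LineString"
        assert {"med_km", "ed_km", "mce", "accumulated_cost"} <= \
            set(f["properties"])
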