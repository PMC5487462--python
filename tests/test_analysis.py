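"""Analysis operators: normalisation, curvature, rates, clustering, fits."""

import math

import numpy as np
import pytest

from passdyn.analysis import (
    NormalizedTrajectory,
    curvature_area,
    fit_radial_distribution,
    optimal_clusters,
    pass_locations,
    pass_rate_by_target,
    point_biserial,
    time_normalize,
    trajectory_heatmap,
    transition_point,
    velocity_profile,
)
from passdyn.movement import Trajectory
from passdyn.task import Point2


def _traj(t, x, y, cls="target"):
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return Trajectory(
        t=t,
        x=x,
        y=y,
        heading=np.zeros_like(t),
        speed=np.zeros_like(t),
        goal=Point2(float(x[-1]), float(y[-1])),
        movement_class=cls,
    )


def _line_traj(n=20, speed=0.5, angle=0.0):
    t = np.linspace(0, 1, n)
    return _traj(t, speed * t * math.cos(angle), speed * t * math.sin(angle))


class TestTimeNormalize:
    def test_length_and_endpoints(self):
        nt = time_normalize(_line_traj(), n=512)
        assert nt.points.shape == (512, 2)
        assert np.allclose(nt.points[0], (0, 0))
        assert np.allclose(nt.points[-1], (0.5, 0))

    def test_straight_constant_velocity_stays_collinear_uniform(self):
        nt = time_normalize(_line_traj(angle=0.4), n=64)
        d = np.diff(nt.points, axis=0)
        # uniform spacing and a fixed direction
        steps = np.hypot(d[:, 0], d[:, 1])
        assert np.allclose(steps, steps[0], atol=1e-12)
        angles = np.arctan2(d[:, 1], d[:, 0])
        assert np.allclose(angles, 0.4, atol=1e-9)

    def test_n2_returns_endpoints(self):
        nt = time_normalize(_line_traj(), n=2)
        assert nt.points.shape == (2, 2)
        assert np.allclose(nt.points, [(0, 0), (0.5, 0)])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            time_normalize(_traj([0, 0.1, 0.2], [0, 1, 2], [0, 0, 0]))


class TestCurvatureArea:
    def test_chord_path_has_zero_area(self):
        nt = time_normalize(_line_traj(angle=0.7), n=512)
        res = curvature_area(nt)
        assert res.area == pytest.approx(0.0, abs=1e-12)
        assert res.deviation == pytest.approx(0.0, abs=1e-6)

    def test_triangle_path_area(self):
        # piecewise-linear bump of height 0.2 over a unit chord: area 0.1
        pts = np.concatenate(
            [
                np.column_stack([np.linspace(0, 0.5, 300), np.linspace(0, 0.2, 300)]),
                np.column_stack(
                    [np.linspace(0.5, 1.0, 300), np.linspace(0.2, 0.0, 300)]
                ),
            ]
        )
        res = curvature_area(NormalizedTrajectory(points=pts))
        assert res.area == pytest.approx(0.1, abs=1e-3)

    def test_below_chord_is_negative(self):
        pts = np.column_stack(
            [np.linspace(0, 1, 512), -0.2 * np.sin(np.pi * np.linspace(0, 1, 512))]
        )
        assert curvature_area(NormalizedTrajectory(points=pts)).area < 0

    def test_right_to_left_initial_angle_180(self):
        nt = time_normalize(_line_traj(angle=math.pi), n=512)
        res = curvature_area(nt)
        assert res.initial_angle == pytest.approx(180.0)
        assert res.straight_line_angle == pytest.approx(180.0)

    def test_coincident_endpoints_rejected(self):
        theta = np.linspace(0, 2 * np.pi, 100)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        with pytest.raises(ValueError):
            curvature_area(NormalizedTrajectory(points=pts))


class TestVelocityProfile:
    def test_constant_speed_flat_profile(self):
        prof = velocity_profile(_line_traj(n=50, speed=0.8), n=128)
        assert np.allclose(prof.profile, 0.8, atol=1e-9)
        assert prof.peak == pytest.approx(0.8)

    def test_reversed_time_rejected(self):
        tr = _line_traj(n=20)
        tr.t = tr.t[::-1]
        with pytest.raises(ValueError):
            velocity_profile(tr)

    def test_simulated_target_movement_peaks_early(self, default_session):
        tr = next(
            t.transport_trajectory
            for t in default_session.trials
            if t.decision == "no_pass"
        )
        assert velocity_profile(tr).peak_fraction < 0.5


class TestPassRates:
    def test_published_denominators_per_block(self, default_session):
        asc = pass_rate_by_target(default_session, "ascending", blocks=[1])
        rnd = pass_rate_by_target(default_session, "random")
        assert np.all(asc.counts == 5)
        assert np.all(rnd.counts == 10)

    def test_rates_bounded_and_trending(self, default_session):
        tab = pass_rate_by_target(default_session, "ascending")
        assert np.all((tab.rates >= 0) & (tab.rates <= 1))
        # monotone non-decreasing trend with target distance
        assert np.all(np.diff(tab.rates) >= 0)

    def test_missing_condition_rejected(self, default_session):
        with pytest.raises(ValueError):
            pass_rate_by_target(default_session, "shuffled")


class TestTransitionPoint:
    def test_step_rates_cross_midway(self):
        ys = np.linspace(-0.07, 0.595, 20)
        rates = np.array([0.0] * 10 + [1.0] * 10)
        est = transition_point(rates, ys, reach=0.522)
        expected_y = 0.5 * (ys[9] + ys[10])
        assert est.transition_target_y == pytest.approx(expected_y)
        assert est.transition_ea == pytest.approx(expected_y / 0.522)

    def test_all_zero_rates_sentinel(self):
        ys = np.linspace(0, 1, 20)
        assert transition_point(np.zeros(20), ys, reach=0.5) is None

    def test_fractional_crossing_interpolates(self):
        ys = np.array([0.1, 0.2, 0.3])
        rates = np.array([0.0, 0.25, 1.0])
        est = transition_point(rates, ys, reach=1.0)
        # crossing between 0.25 and 1.0: y = 0.2 + (0.25/0.75)*0.1
        assert est.transition_target_y == pytest.approx(0.2 + 0.1 / 3)


class TestPointBiserial:
    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=500)
        b = (c + rng.normal(scale=0.5, size=500) > 0).astype(int)
        r = point_biserial(b, c)
        bm, cm = b - b.mean(), c - c.mean()
        pearson = np.sum(bm * cm) / np.sqrt(np.sum(bm**2) * np.sum(cm**2))
        assert r == pytest.approx(pearson, abs=1e-12)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(1)
        b = rng.integers(0, 2, size=10_000)
        c = rng.normal(size=10_000)
        assert abs(point_biserial(b, c)) < 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            point_biserial(np.ones(10), np.arange(10))


class TestHeatmap:
    def test_single_stationary_sample(self):
        tr = _traj([0.0], [0.25], [0.25])
        grid = trajectory_heatmap([tr], 10, 10, (0, 1, 0, 1))
        assert grid.sum() == 1
        assert grid[2, 2] == 1

    def test_counts_conserved_within_bounds(self, default_session):
        trajs = [t.pickup_trajectory for t in default_session.trials[:50]]
        n_samples = sum(len(t) for t in trajs)
        grid = trajectory_heatmap(trajs, 930, 510, (-0.4, 1.2, -0.2, 0.8))
        assert grid.shape == (930, 510)
        assert grid.sum() <= n_samples
        assert grid.sum() >= 0.95 * n_samples

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            trajectory_heatmap([], 10, 10, (0, 0, 0, 1))


class TestClusters:
    def test_single_blob_prefers_k1(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(loc=(0.5, 0.5), scale=0.01, size=(200, 2))
        res = optimal_clusters(pts, n_ref=30, rng=0)
        assert res.optimal_k == 1

    def test_two_separated_blobs_prefer_k2(self):
        rng = np.random.default_rng(4)
        a = rng.normal(loc=(0.0, 0.0), scale=0.02, size=(100, 2))
        b = rng.normal(loc=(1.0, 1.0), scale=0.02, size=(100, 2))
        res = optimal_clusters(np.vstack([a, b]), n_ref=30, rng=0)
        assert res.optimal_k == 2

    def test_sse_non_increasing_in_k(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(120, 2))
        res = optimal_clusters(pts, n_ref=10, rng=0)
        sses = [res.sse_by_k[k] for k in sorted(res.sse_by_k)]
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            optimal_clusters(np.zeros((2, 2)), k_max=3)


class TestRadialFit:
    def test_lognormal_radius_cloud_best_fit(self):
        rng = np.random.default_rng(6)
        r = rng.lognormal(mean=math.log(0.05), sigma=0.5, size=500)
        phi = rng.uniform(0, 2 * np.pi, size=500)
        pts = np.column_stack([0.5 + r * np.cos(phi), 0.5 + r * np.sin(phi)])
        res = fit_radial_distribution(pts)
        assert res.best_family == "lognormal"
        assert res.fits["lognormal"].p_value > 0.1

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(100, 2))
        res = fit_radial_distribution(pts)
        for fit in res.fits.values():
            assert 0.0 <= fit.p_value <= 1.0

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            fit_radial_distribution(np.tile([0.3, 0.3], (20, 1)))


class TestSessionLevelPatterns:
    def test_decision_correlations_match_observed_pattern(self, default_session):
        # target drives decisions; pickup does not
        dec = default_session.decisions()
        r_t = point_biserial(dec, [t.spec.target_index for t in default_session.trials])
        r_p = point_biserial(dec, [t.spec.pickup_index for t in default_session.trials])
        assert r_t > 0.7
        assert abs(r_p) < 0.1

    def test_pickup_curvature_flips_sign_with_distance(self, default_session):
        areas = {i: [] for i in range(1, 6)}
        for t in default_session.trials:
            res = curvature_area(time_normalize(t.pickup_trajectory))
            areas[t.spec.pickup_index].append(res.area)
        means = [np.mean(areas[i]) for i in range(1, 6)]
        assert means[0] > 0
        assert means[-1] < 0

    def test_transition_recovers_decision_centre(self, default_session):
        # random presentation averages the hysteresis out, so its 50 %
        # crossing estimates sigma
        tab = pass_rate_by_target(default_session, "random")
        est = transition_point(
            tab.rates, tab.target_ys, default_session.task.reach, "random"
        )
        sigma = default_session.params.decision.sigma
        assert est.transition_ea == pytest.approx(sigma, abs=0.02)

    def test_pass_locations_cluster_around_anchor(self, default_session):
        pl = pass_locations(default_session, frame="table")
        assert len(pl) > 100
        anchor = default_session.task.pass_anchor_near_target
        assert np.hypot(*(pl.mean(axis=0) - (anchor.x, anchor.y))) < 0.05
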