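"""Circle fitting, central angle, Cobb-equivalent conversion, QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kyphometry import (
    CollinearPointsError,
    DegenerateAngleError,
    FittedCircle,
    InsufficientPointsError,
    MeasurementConfig,
    Point2D,
    VertebraLevel,
    VertebralCentroidSet,
    central_angle,
    classify_kyphosis,
    cobb_from_tangents,
    fit_circle,
    measure_kyphosis,
)

from conftest import arc_points, brute_force_circle_fit


def make_set(points, scan_id="s1", skip=()):
    cs = VertebralCentroidSet(scan_id=scan_id)
    for lvl, p in zip(VertebraLevel, points):
        if lvl in skip:
            continue
        cs.add(lvl, Point2D(float(p[0]), float(p[1])))
    return cs


class TestFitCircle:
    @pytest.mark.parametrize("method", ["algebraic", "geometric-refined"])
    def test_circumscribed_circle_of_symmetric_points(self, method):
        c = fit_circle([(1, 0), (0, 1), (-1, 0)], method)
        assert c.center.x == pytest.approx(0, abs=1e-12)
        assert c.center.y == pytest.approx(0, abs=1e-12)
        assert c.radius == pytest.approx(1, abs=1e-12)
        assert c.rms_residual < 1e-12
        assert c.n_points == 3

    @pytest.mark.parametrize("method", ["algebraic", "geometric-refined"])
    def test_exact_arc_recovery(self, method):
        pts = arc_points(60.0, radius=55.0, center=(12.5, -40.0))
        c = fit_circle(pts, method)
        assert c.center.x == pytest.approx(12.5, abs=1e-6)
        assert c.center.y == pytest.approx(-40.0, abs=1e-6)
        assert c.radius == pytest.approx(55.0, abs=1e-6)
        assert c.rms_residual < 1e-9

    @pytest.mark.parametrize("method", ["algebraic", "geometric-refined"])
    def test_pure_radial_inflation_preserves_circularity(self, method):
        # pushing every point radially outward by +0.3 yields the same
        # center with radius 55.3 and zero residual
        pts = arc_points(60.0, radius=55.3, center=(12.5, -40.0))
        c = fit_circle(pts, method)
        assert c.radius == pytest.approx(55.3, abs=1e-6)
        assert c.rms_residual < 1e-9
        # cross-check against the independent brute-force oracle
        bx, by, br = brute_force_circle_fit(pts)
        assert c.center.x == pytest.approx(bx, abs=1e-5)
        assert c.center.y == pytest.approx(by, abs=1e-5)
        assert c.radius == pytest.approx(br, abs=1e-5)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            fit_circle([(0, 0), (1, 1)])

    def test_collinear_points(self):
        with pytest.raises(CollinearPointsError):
            fit_circle([(i, 2 * i) for i in range(9)])

    def test_identical_points_are_degenerate(self):
        with pytest.raises(CollinearPointsError):
            fit_circle([(1.0, 1.0)] * 5)

    def test_nonfinite_points_rejected(self):
        with pytest.raises(ValueError):
            fit_circle([(0, 0), (1, float("nan")), (0, 1)])

    def test_geometric_refinement_never_worse_than_seed(self, rng):
        # on noisy data the geometric fit's radial SSE is <= the Kasa seed's
        pts = arc_points(50.0) + rng.normal(0, 0.5, (9, 2))

        def sse(circle):
            d = np.hypot(pts[:, 0] - circle.center.x, pts[:, 1] - circle.center.y)
            return np.sum((d - circle.radius) ** 2)

        assert sse(fit_circle(pts, "geometric-refined")) <= sse(
            fit_circle(pts, "algebraic")
        ) + 1e-12


class TestAngles:
    def setup_method(self):
        self.unit = FittedCircle(Point2D(0, 0), 1.0, 0.0, 9)

    def test_perpendicular_radii(self):
        assert central_angle(self.unit, Point2D(1, 0), Point2D(0, 1)) == pytest.approx(
            90.0, abs=1e-12
        )

    def test_diameter(self):
        assert central_angle(
            self.unit, Point2D(1, 0), Point2D(-1, 0)
        ) == pytest.approx(180.0, abs=1e-12)

    def test_analytic_angle_difference(self):
        c = FittedCircle(Point2D(3, 4), 5.0, 0.0, 9)
        p1 = Point2D(3 + 5 * math.cos(math.radians(10)), 4 + 5 * math.sin(math.radians(10)))
        p2 = Point2D(3 + 5 * math.cos(math.radians(55)), 4 + 5 * math.sin(math.radians(55)))
        got = central_angle(c, p1, p2)
        assert got == pytest.approx(45.0, abs=1e-9)
        # chord-formula cross-check: theta = 2*arcsin(chord / (2 r))
        chord = math.dist(p1, p2)
        assert got == pytest.approx(
            math.degrees(2 * math.asin(chord / 10.0)), abs=1e-9
        )

    def test_center_point_is_degenerate(self):
        with pytest.raises(DegenerateAngleError):
            central_angle(self.unit, Point2D(0, 0), Point2D(1, 0))
        with pytest.raises(DegenerateAngleError):
            central_angle(self.unit, Point2D(1, 0), Point2D(1, 0))

    def test_tangent_angle_equals_central_angle(self):
        assert cobb_from_tangents(
            self.unit, Point2D(1, 0), Point2D(0, 1)
        ) == pytest.approx(90.0, abs=1e-12)

    def test_antipodal_parallel_tangents(self):
        c = FittedCircle(Point2D(2, -3), 7.0, 0.0, 9)
        assert cobb_from_tangents(
            c, Point2D(9, -3), Point2D(-5, -3)
        ) == pytest.approx(180.0, abs=1e-12)

    def test_tangent_identity_over_random_circles(self, rng):
        # the tangent-tangent angle equals the central angle for endpoints
        # on the circle, across 1000 random circle/endpoint configurations
        worst = 0.0
        for _ in range(1000):
            cx, cy = rng.uniform(-100, 100, 2)
            r = rng.uniform(0.1, 500)
            a, b = rng.uniform(0, 2 * np.pi, 2)
            circle = FittedCircle(Point2D(cx, cy), r, 0.0, 9)
            p1 = Point2D(cx + r * np.cos(a), cy + r * np.sin(a))
            p2 = Point2D(cx + r * np.cos(b), cy + r * np.sin(b))
            if p1 == p2:
                continue
            worst = max(
                worst,
                abs(cobb_from_tangents(circle, p1, p2) - central_angle(circle, p1, p2)),
            )
        assert worst < 1e-9

    def test_fixed_chord_smaller_radius_larger_angle(self):
        # circles through the chord (-1,0)-(1,0): theta strictly increases
        # as the fitted radius decreases
        angles = []
        for r in [10.0, 5.0, 2.0, 1.5, 1.01]:
            h = math.sqrt(r * r - 1.0)
            c = FittedCircle(Point2D(0, -h), r, 0.0, 9)
            angles.append(central_angle(c, Point2D(-1, 0), Point2D(1, 0)))
        assert all(a < b for a, b in zip(angles, angles[1:]))


class TestMeasureKyphosis:
    def test_exact_recovery_of_generating_angle(self):
        pts = arc_points(46.1, radius=55.0)
        m = measure_kyphosis(make_set(pts))
        assert m.qc_flag == "ok"
        assert m.central_angle_deg == pytest.approx(46.1, abs=1e-6)
        assert m.cobb_equiv_deg == pytest.approx(m.central_angle_deg, abs=1e-9)
        assert m.levels_used == tuple(VertebraLevel)
        assert m.circle is not None and m.circle.rms_residual < 1e-9

    def test_missing_level_flags_unsuitable(self):
        pts = arc_points(46.1)
        m = measure_kyphosis(make_set(pts, skip={VertebraLevel.TH12}))
        assert m.qc_flag == "unsuitable"
        assert "Th12" in m.qc_reason
        assert m.central_angle_deg is None and m.cobb_equiv_deg is None

    def test_collinear_chain_flags_unsuitable(self):
        pts = [(float(i), 10.0 + 3.0 * i) for i in range(9)]
        m = measure_kyphosis(make_set(pts))
        assert m.qc_flag == "unsuitable"
        assert "collinear" in m.qc_reason

    def test_nearly_straight_arc_is_finite_and_accurate(self):
        pts = arc_points(0.5, radius=300.0, center=(500.0, 320.0))
        m = measure_kyphosis(make_set(pts))
        assert m.qc_flag == "ok"
        assert m.central_angle_deg == pytest.approx(0.5, abs=1e-3)
        # chord-formula oracle on the fitted circle
        chord = math.dist(pts[0], pts[-1])
        expected = math.degrees(2 * math.asin(chord / (2 * m.circle.radius)))
        assert m.central_angle_deg == pytest.approx(expected, abs=1e-6)

    def test_interior_point_across_chord_flags_geometry(self):
        # reflect one interior centroid across the Th4-Th12 chord: the chain
        # is no longer convex toward the fitted arc
        pts = arc_points(60.0, radius=55.0).copy()
        p0, p1 = pts[0], pts[-1]
        chord = p1 - p0
        u = chord / np.linalg.norm(chord)
        v = pts[4] - p0
        pts[4] = p0 + 2 * (v @ u) * u - v
        m = measure_kyphosis(make_set(pts))
        assert m.qc_flag == "unsuitable"
        assert "geometry" in m.qc_reason

    @settings(max_examples=40, derandomize=True)
    @given(
        angle=st.floats(1.5, 120.0),
        rot=st.floats(0, 2 * math.pi),
        tx=st.floats(-1e3, 1e3),
        ty=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 100.0),
    )
    def test_similarity_invariance(self, angle, rot, tx, ty, scale):
        pts = arc_points(angle, radius=55.0)
        base = measure_kyphosis(make_set(pts)).central_angle_deg
        R = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])
        moved = scale * pts @ R.T + np.array([tx, ty])
        got = measure_kyphosis(make_set(moved)).central_angle_deg
        assert got == pytest.approx(base, abs=1e-9)

    def test_reflection_invariance(self):
        pts = arc_points(46.1, radius=55.0)
        mirrored = pts * np.array([-1.0, 1.0])
        a = measure_kyphosis(make_set(pts)).central_angle_deg
        b = measure_kyphosis(make_set(mirrored)).central_angle_deg
        assert a == pytest.approx(b, abs=1e-9)

    def test_noise_error_is_unbiased_and_near_information_bound(self):
        # 9 centroids, sd 1 px on radius 300 px, theta*=45.3: the Fisher
        # information of the arc model bounds sd(theta_hat) at ~1.76 deg;
        # the geometric fit should be unbiased and within ~1.5x of the bound
        from kyphometry.synthetic import PhantomSpec, make_centroids

        cfg = MeasurementConfig(fit_method="geometric-refined")
        errs = []
        for seed in range(300):
            spec = PhantomSpec(
                true_central_angle_deg=45.3, centroid_noise_sd=1.0, seed=seed
            )
            obs, _ = make_centroids(spec)
            m = measure_kyphosis(obs, cfg)
            errs.append(m.central_angle_deg - 45.3)
        errs = np.asarray(errs)
        assert abs(errs.mean()) < 0.35  # ~3 SE at sd 1.9, n 300
        assert 1.4 < errs.std() < 2.6


@pytest.mark.parametrize(
    "angle,expected",
    [(45.3, "significant"), (35.2, "not_significant"), (40.0, "significant")],
)
def test_classify_kyphosis_threshold_inclusive(angle, expected):
    assert classify_kyphosis(angle) == expected


def test_classify_kyphosis_custom_threshold_and_validation():
    assert classify_kyphosis(45.0, threshold_deg=50.0) == "not_significant"
    with pytest.raises(ValueError):
        classify_kyphosis(float("nan"))
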