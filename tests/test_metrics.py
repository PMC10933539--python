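"""Structural metrics: heights, circle fits, hull diameters, crown volume."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tlscarbon import (
    DegenerateCrownError,
    FitError,
    InsufficientPointsError,
    MetricsConfig,
    PointCloud,
    compute_all_metrics,
    crown_volume,
    estimate_dbh,
    estimate_dtb,
    estimate_fdbh,
    fit_circle_algebraic,
    fit_circle_ls,
    read_metrics_table,
    slice_cloud,
    tree_height,
    write_metrics_table,
)
from tlscarbon.metrics import StructuralMetrics

from .conftest import circle_points, make_cone, make_cylinder


# ---------------------------------------------------------------------------
# height and slicing
# ---------------------------------------------------------------------------

class TestHeight:
    def test_vertical_extent(self):
        cloud = PointCloud(np.array([[0, 0, 0.0], [1, 1, 54.87]]))
        assert tree_height(cloud) == pytest.approx(54.87)

    def test_degenerate_flat_cloud(self):
        cloud = PointCloud(np.tile([[1.0, 2.0, 3.0]], (5, 1)))
        assert tree_height(cloud) == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 30, (500, 3))
        cloud = PointCloud(pts)
        shifted = PointCloud(pts + [5.0, -3.0, 100.0])
        assert tree_height(shifted) == pytest.approx(tree_height(cloud), abs=1e-9)


class TestSliceCloud:
    def test_uniform_cylinder_slice_count(self):
        """A 0.2 m slab of a uniformly sampled 10 m cylinder holds ~2% of points."""
        cloud = make_cylinder(radius=0.5, height=10.0, spacing=0.02)
        section = slice_cloud(cloud, 1.2, 1.4)
        expected = len(cloud) * 0.2 / 10.0
        assert abs(section.n_points - expected) < 4 * math.sqrt(expected)

    def test_slice_above_treetop_errors(self):
        cloud = make_cylinder(height=3.0)
        with pytest.raises(InsufficientPointsError) as err:
            slice_cloud(cloud, 4.0, 4.5)
        assert err.value.count == 0

    def test_half_open_upper_bound(self):
        """A point exactly at z_high is excluded from the slab."""
        base = np.tile([[0.0, 0.0, 0.0]], (30, 1))
        ring = np.column_stack([np.ones(30), np.zeros(30), np.full(30, 1.4)])
        cloud = PointCloud(np.vstack([base, ring]))
        section = slice_cloud(cloud, 0.0, 1.4, min_points=5)
        assert section.n_points == 30  # only the z=0 block


# ---------------------------------------------------------------------------
# circle fitting
# ---------------------------------------------------------------------------

class TestCircleFit:
    def test_exact_circle_recovered_to_1e9(self):
        xy = circle_points(3.0, -2.0, 0.75, 100)
        fit = fit_circle_ls(xy)
        assert fit.cx == pytest.approx(3.0, abs=1e-9)
        assert fit.cy == pytest.approx(-2.0, abs=1e-9)
        assert fit.radius == pytest.approx(0.75, abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_noisy_circle_monte_carlo(self):
        """Full circle, 500 points, isotropic sd 0.01: radius within 0.005."""
        errs = [
            abs(fit_circle_ls(circle_points(0, 0, 0.75, 500, noise_sd=0.01,
                                            seed=s)).radius - 0.75)
            for s in range(100)
        ]
        assert max(errs) < 0.005

    def test_semicircular_arc_within_2pct(self):
        """An occluded stem leaving 180 degrees of arc still fits to 2%."""
        errs = [
            abs(fit_circle_ls(circle_points(0, 0, 0.6, 250, arc=math.pi,
                                            noise_sd=0.005, seed=s)).radius - 0.6)
            for s in range(100)
        ]
        assert max(errs) < 0.02 * 0.6

    def test_collinear_points_fail(self):
        xy = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 2, 50)])
        with pytest.raises(FitError, match="collinear|degenerate"):
            fit_circle_ls(xy)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_geometric_fit_refines_algebraic(self, seed):
        """The geometric objective never exceeds the Kåsa fit it starts from."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        xy = circle_points(
            float(rng.uniform(-5, 5)), float(rng.uniform(-5, 5)),
            float(rng.uniform(0.2, 2.0)), n,
            arc=float(rng.uniform(math.pi / 2, 2 * math.pi)),
            noise_sd=float(rng.uniform(0, 0.05)), seed=seed,
        )

        def objective(cx, cy, r):
            return float(((np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) - r) ** 2).sum())

        geo = fit_circle_ls(xy)
        assert objective(geo.cx, geo.cy, geo.radius) <= (
            objective(*fit_circle_algebraic(xy)) + 1e-12
        )


# ---------------------------------------------------------------------------
# diameters
# ---------------------------------------------------------------------------

class TestDiameters:
    def test_cylinder_dbh_exact(self):
        cloud = make_cylinder(radius=1.0, height=6.0)
        assert estimate_dbh(cloud) == pytest.approx(2.0, abs=1e-8)
        assert estimate_dtb(cloud) == pytest.approx(estimate_dbh(cloud), abs=1e-8)

    def test_cone_dbh_with_small_taper_bias(self):
        """A cone with radius 0.16 m at 1.3 m reads DBH = 0.32 m within 1%."""
        height = 30.0
        base_radius = 0.16 * height / (height - 1.3)
        cloud = make_cone(base_radius=base_radius, height=height, spacing=0.02)
        assert estimate_dbh(cloud) == pytest.approx(0.32, rel=0.01)

    def test_rotation_invariance(self):
        cloud = make_cylinder(radius=0.8, height=6.0, noise_sd=0.004, seed=9)
        a = math.radians(73.0)
        rot = np.array([[math.cos(a), -math.sin(a), 0],
                        [math.sin(a), math.cos(a), 0], [0, 0, 1]])
        rotated = PointCloud(cloud.points @ rot.T)
        assert estimate_dbh(rotated) == pytest.approx(estimate_dbh(cloud), abs=1e-9)

    def test_flared_tree_has_dtb_below_dbh(self, small_tree):
        cloud, truth = small_tree
        dbh, dtb = estimate_dbh(cloud), estimate_dtb(cloud)
        assert dtb < dbh
        assert dbh == pytest.approx(truth.dbh_true, rel=0.02)
        assert dtb == pytest.approx(truth.dtb_true, rel=0.02)

    def test_short_tree_has_no_dtb(self):
        cloud = make_cylinder(radius=0.3, height=3.5)
        with pytest.raises(InsufficientPointsError):
            estimate_dtb(cloud)


class TestFunctionalDbh:
    def test_dense_circle_boundary(self):
        """fDBH of a dense circular section approaches the true diameter."""
        ring = circle_points(0, 0, 0.5, 2000)
        cloud = PointCloud(np.column_stack([ring, np.full(len(ring), 1.3)]))
        assert estimate_fdbh(cloud, (0.0, 2.0)) == pytest.approx(1.0, rel=2e-3)

    def test_elliptical_section(self):
        """Ellipse with semi-axes 0.6 and 0.4: fDBH = 2*sqrt(0.6*0.4)."""
        theta = np.linspace(0, 2 * math.pi, 1500, endpoint=False)
        xy = np.column_stack([0.6 * np.cos(theta), 0.4 * np.sin(theta)])
        cloud = PointCloud(np.column_stack([xy, np.full(len(xy), 1.3)]))
        assert estimate_fdbh(cloud, (0.0, 2.0)) == pytest.approx(
            2 * math.sqrt(0.6 * 0.4), rel=2e-3
        )

    def test_square_section(self):
        """Corner points of a unit square: hull area 1, fDBH = 2/sqrt(pi)."""
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        xy = np.vstack([corners] * 5)  # meet the 20-point slice minimum
        cloud = PointCloud(np.column_stack([xy, np.full(len(xy), 1.3)]))
        assert estimate_fdbh(cloud, (0.0, 2.0)) == pytest.approx(
            2 * math.sqrt(1 / math.pi), abs=1e-9
        )


# ---------------------------------------------------------------------------
# crown volume
# ---------------------------------------------------------------------------

class TestCrownVolume:
    def test_unit_cube_corners(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float
        )
        assert crown_volume(PointCloud(corners), crown_base=0.0) == pytest.approx(1.0)

    def test_prolate_spheroid_convergence(self):
        """Dense samples of a (2, 2, 8) spheroid hull to (4/3)*pi*2*2*8."""
        rng = np.random.default_rng(1)
        u = rng.uniform(-1, 1, 20000)
        theta = rng.uniform(0, 2 * math.pi, 20000)
        s = np.sqrt(1 - u**2)
        pts = np.column_stack([2 * s * np.cos(theta), 2 * s * np.sin(theta), 8 * u])
        vol = crown_volume(PointCloud(pts), crown_base=0.0)
        assert vol == pytest.approx(4 / 3 * math.pi * 2 * 2 * 8, rel=0.01)

    def test_crown_base_above_treetop(self):
        cloud = make_cylinder(height=5.0)
        with pytest.raises(DegenerateCrownError):
            crown_volume(cloud, crown_base=50.0)

    def test_fixture_crown_volume_near_truth(self, small_tree):
        cloud, truth = small_tree
        vol = crown_volume(cloud)  # auto-detected crown base
        assert vol == pytest.approx(truth.crown_volume_true, rel=0.10)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestComputeAllMetrics:
    def test_fixture_metrics_within_tolerance(self, small_tree, small_tree_spec):
        cloud, truth = small_tree
        m = compute_all_metrics(cloud, tree_id="fixture")
        assert m.height == pytest.approx(truth.height_true, rel=0.01)
        assert m.dbh == pytest.approx(truth.dbh_true, rel=0.02)
        assert m.dtb == pytest.approx(truth.dtb_true, rel=0.02)
        assert m.fdbh == pytest.approx(truth.fdbh_true, rel=0.03)
        assert m.crown_volume == pytest.approx(truth.crown_volume_true, rel=0.10)
        assert m.woody_volume == pytest.approx(truth.woody_volume_true, rel=0.05)
        assert m.volume_sd >= 0

    def test_tiny_cloud_reports_height_only(self):
        rng = np.random.default_rng(2)
        cloud = PointCloud(rng.uniform(0, 5, (50, 3)))
        m = compute_all_metrics(cloud, MetricsConfig(estimate_volume=False))
        assert m.height is not None
        assert m.dbh is None and m.dtb is None and m.fdbh is None
        assert "dbh" in m.errors and "50 points" in m.errors["dbh"]

    def test_deterministic_rerun(self, small_tree):
        cloud, _ = small_tree
        config = MetricsConfig(volume_seed=4)
        m1 = compute_all_metrics(cloud, config)
        m2 = compute_all_metrics(cloud, config)
        assert (m1.height, m1.dbh, m1.dtb, m1.fdbh, m1.crown_volume,
                m1.woody_volume, m1.volume_sd) == (
            m2.height, m2.dbh, m2.dtb, m2.fdbh, m2.crown_volume,
            m2.woody_volume, m2.volume_sd)

    def test_metrics_table_round_trip(self, tmp_path):
        rows = [StructuralMetrics(tree_id="T1", height=20.0, dbh=0.9,
                                  woody_volume=5.0, volume_sd=0.1),
                StructuralMetrics(tree_id="T2", height=10.0)]
        path = tmp_path / "metrics.csv"
        write_metrics_table(rows, path)
        back = read_metrics_table(path)
        assert back[0].dbh == pytest.approx(0.9)
        assert back[1].dbh is None and back[1].height == pytest.approx(10.0)
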