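"""Geometry: poses, projection, quad areas, arrangement sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agrocam.geometry import (
    ArrangementTable,
    CameraExtrinsics,
    CameraIntrinsics,
    CameraModel,
    GroundROI,
    NonProjectableError,
    QuadProjection,
    build_pose,
    project_point,
    project_roi,
    quad_pixel_area,
    rasterize_pixel_count,
    recommend_arrangement,
    sweep_arrangements,
)
from agrocam.synthscene import make_table1_fixture


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestBuildPose:
    def test_nadir_optical_axis_points_straight_down(self):
        pose = build_pose(CameraExtrinsics(pitch_alpha_deg=90.0, height_h_cm=200.0))
        # camera z axis (third row of R) expressed in world coordinates
        np.testing.assert_allclose(pose.rotation[2], [0.0, 0.0, -1.0], atol=1e-12)

    @given(
        alpha=st.floats(1.0, 90.0),
        theta=st.floats(-30.0, 30.0),
        beta=st.floats(-45.0, 45.0),
        h=st.floats(50.0, 400.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_rotation_is_orthonormal(self, alpha, theta, beta, h):
        pose = build_pose(
            CameraExtrinsics(
                pitch_alpha_deg=alpha,
                height_h_cm=h,
                roll_theta_deg=theta,
                yaw_beta_deg=beta,
            )
        )
        r = pose.rotation
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_matches_elemental_rotation_product(self):
        """Independent oracle: compose base orientation with explicit
        elemental yaw/pitch/roll matrices."""
        alpha, theta, beta = np.deg2rad([30.0, 7.0, -12.0])
        base = np.array([[0.0, -1.0, 0.0], [0.0, 0.0, -1.0], [1.0, 0.0, 0.0]])
        expected = _rot_z(theta) @ _rot_x(alpha) @ base @ _rot_z(-beta)
        pose = build_pose(
            CameraExtrinsics(
                pitch_alpha_deg=30.0,
                height_h_cm=220.0,
                roll_theta_deg=7.0,
                yaw_beta_deg=-12.0,
            )
        )
        np.testing.assert_allclose(pose.rotation, expected, atol=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, -10.0, 90.5, 180.0])
    def test_rejects_pitch_outside_interval(self, alpha):
        with pytest.raises(ValueError):
            CameraExtrinsics(pitch_alpha_deg=alpha, height_h_cm=220.0)


class TestProjectPoint:
    def test_nadir_point_beneath_camera_maps_to_principal_point(self, intrinsics):
        cam = CameraModel(
            intrinsics, CameraExtrinsics(pitch_alpha_deg=90.0, height_h_cm=200.0)
        )
        u, v = project_point([0.0, 0.0, 0.0], cam)
        assert (u, v) == pytest.approx(intrinsics.principal)

    def test_rectilinear_lateral_offset_similar_triangles(
        self, rectilinear_intrinsics
    ):
        """Nadir at h = 2 m, point 1 m to the side: pixel offset is
        (f * X / h) / pitch = (0.01 * 1 / 2) / 5.5e-6 = 909.09 px."""
        cam = CameraModel(
            rectilinear_intrinsics,
            CameraExtrinsics(pitch_alpha_deg=90.0, height_h_cm=200.0),
        )
        u, v = project_point([0.0, 1.0, 0.0], cam)
        cx, cy = rectilinear_intrinsics.principal
        assert abs(u - cx) == pytest.approx(909.0909, abs=1e-3)
        assert v == pytest.approx(cy, abs=1e-9)

    def test_equidistant_lateral_offset_f_theta(self, intrinsics):
        """Same geometry under the wide-angle law: radius = f * theta."""
        cam = CameraModel(
            intrinsics, CameraExtrinsics(pitch_alpha_deg=90.0, height_h_cm=200.0)
        )
        u, v = project_point([0.0, 1.0, 0.0], cam)
        cx, _ = intrinsics.principal
        expected = intrinsics.focal_px * np.arctan(0.5)
        assert abs(u - cx) == pytest.approx(expected, rel=1e-12)

    def test_point_behind_camera_raises(self, intrinsics):
        cam = CameraModel(
            intrinsics, CameraExtrinsics(pitch_alpha_deg=45.0, height_h_cm=220.0)
        )
        with pytest.raises(NonProjectableError):
            project_point([-5.0, 0.0, 0.0], cam)


class TestProjectRoi:
    def test_nadir_centered_square_is_centered_square(self, intrinsics):
        cam = CameraModel(
            intrinsics, CameraExtrinsics(pitch_alpha_deg=90.0, height_h_cm=300.0)
        )
        # nadir view: the square directly beneath the camera
        roi = GroundROI(distance_d_m=0.5, width_m=1.0, depth_m=1.0,
                        lateral_offset_m=0.0)
        # shift so the square is centred under the camera
        roi = GroundROI(distance_d_m=1e-9 + 0.5, width_m=1.0, depth_m=1.0) \
            if False else roi
        quad = project_roi(roi, cam)
        cx, cy = intrinsics.principal
        # symmetric about the vertical centreline
        us = np.sort(quad.corners_px[:, 0])
        assert us[0] + us[-1] == pytest.approx(2 * cx, abs=1e-6)

    def test_oblique_view_foreshortens_far_edge(self, intrinsics):
        cam = CameraModel(
            intrinsics, CameraExtrinsics(pitch_alpha_deg=50.0, height_h_cm=230.0)
        )
        quad = project_roi(GroundROI(distance_d_m=3.0), cam)
        c = quad.corners_px
        order = np.argsort(c[:, 1])
        far = c[order[:2]]   # smaller v = higher in image = farther
        near = c[order[2:]]
        far_w = abs(far[0, 0] - far[1, 0])
        near_w = abs(near[0, 0] - near[1, 0])
        assert far_w < near_w

    def test_corners_match_individual_point_projection(self, intrinsics):
        cam = CameraModel(
            intrinsics, CameraExtrinsics(pitch_alpha_deg=40.0, height_h_cm=215.0)
        )
        roi = GroundROI(distance_d_m=4.0, lateral_offset_m=0.3)
        quad = project_roi(roi, cam)
        individual = np.array(
            [project_point(p, cam) for p in roi.corners_world()]
        )
        # same cyclic set of corners
        for corner in individual:
            dists = np.linalg.norm(quad.corners_px - corner, axis=1)
            assert dists.min() < 1e-9

    def test_ordering_is_counter_clockwise(self, intrinsics):
        cam = CameraModel(
            intrinsics, CameraExtrinsics(pitch_alpha_deg=30.0, height_h_cm=220.0)
        )
        quad = project_roi(GroundROI(distance_d_m=3.5), cam)
        u, v = quad.corners_px[:, 0], quad.corners_px[:, 1]
        signed = 0.5 * np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v)
        assert signed > 0

    def test_lateral_mirror_symmetry_at_nadir(self, intrinsics):
        cam = CameraModel(
            intrinsics, CameraExtrinsics(pitch_alpha_deg=90.0, height_h_cm=250.0)
        )
        cx, _ = intrinsics.principal
        left = project_roi(
            GroundROI(distance_d_m=0.3, lateral_offset_m=0.4), cam
        ).corners_px
        right = project_roi(
            GroundROI(distance_d_m=0.3, lateral_offset_m=-0.4), cam
        ).corners_px
        mirrored = sorted((round(2 * cx - u, 6), round(v, 6)) for u, v in left)
        direct = sorted((round(u, 6), round(v, 6)) for u, v in right)
        assert mirrored == direct


class TestQuadArea:
    def test_axis_aligned_square(self):
        quad = QuadProjection(
            corners_px=np.array([[0, 0], [100, 0], [100, 100], [0, 100]], float),
            clipped=False,
        )
        assert quad_pixel_area(quad) == pytest.approx(10_000.0)

    def test_degenerate_collinear_quad_has_zero_area(self):
        quad = QuadProjection(
            corners_px=np.array([[0, 0], [10, 0], [20, 0], [30, 0]], float),
            clipped=False,
        )
        assert quad_pixel_area(quad) == pytest.approx(0.0)

    def test_self_intersecting_quad_rejected(self):
        bowtie = QuadProjection(
            corners_px=np.array([[0, 0], [10, 10], [10, 0], [0, 10]], float),
            clipped=False,
        )
        with pytest.raises(ValueError):
            quad_pixel_area(bowtie)

    def test_clipping_reduces_area_for_offsensor_quad(self, intrinsics):
        quad = QuadProjection(
            corners_px=np.array(
                [[-100, 0], [200, 0], [200, 300], [-100, 300]], float
            ),
            clipped=True,
        )
        full = quad_pixel_area(quad)
        clipped = quad_pixel_area(quad, intrinsics, clip_to_sensor=True)
        assert clipped == pytest.approx(200 * 300)
        assert clipped < full

    def test_shoelace_matches_rasterization_on_random_convex_quads(self, rng):
        """Analytic area vs pixel-centre counting agree within 1.5 % on
        large random convex quads."""
        checked = 0
        while checked < 50:
            center = rng.uniform(200, 800, 2)
            angles = np.sort(rng.uniform(0, 2 * np.pi, 4))
            if np.max(np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))) > np.pi:
                continue  # avoid degenerate angular gaps
            radii = rng.uniform(80, 220, 4)
            pts = center + np.column_stack(
                [radii * np.cos(angles), radii * np.sin(angles)]
            )
            # convexity check via cross products
            d = np.roll(pts, -1, axis=0) - pts
            d2 = np.roll(d, -1, axis=0)
            cross = d[:, 0] * d2[:, 1] - d[:, 1] * d2[:, 0]
            if not (np.all(cross > 0) or np.all(cross < 0)):
                continue
            quad = QuadProjection(corners_px=pts, clipped=False)
            area = quad_pixel_area(quad)
            if area < 10_000:
                continue
            count = rasterize_pixel_count(quad)
            assert count == pytest.approx(area, rel=0.015)
            checked += 1


class TestSweep:
    def test_default_grid_has_125_records(self):
        table = sweep_arrangements(
            [10, 20, 30, 40, 50], [210, 215, 220, 225, 230],
            [3.0, 3.5, 4.0, 4.5, 5.0],
        )
        assert len(table) == 125
        assert table.records["projectable"].all()

    def test_pixel_count_decreases_with_distance(self):
        table = sweep_arrangements([20], [220], [3.0, 3.5, 4.0, 4.5, 5.0])
        n = table.records["n_pixels"].to_numpy()
        assert np.all(np.diff(n) < 0)

    def test_pitch_30_dip_at_3m(self):
        table = sweep_arrangements([10, 30, 50], [215], [3.0])
        n = {
            row.alpha_deg: row.n_pixels for row in table.records.itertuples()
        }
        assert n[30] < n[10] and n[30] < n[50]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_arrangements([], [220], [3.0])


@pytest.fixture(scope="module")
def table1():
    return make_table1_fixture()


class TestRecommend:

    def test_unconstrained_maximum_matches_survey(self, table1):
        best = recommend_arrangement(table1)
        assert (best.alpha_deg, best.height_cm, best.distance_m) == (50, 230, 3.0)
        assert best.n_pixels == 129_423

    def test_minimum_beyond_5m(self, table1):
        worst = recommend_arrangement(table1, min_distance_m=5.0, objective="min")
        assert (worst.alpha_deg, worst.height_cm, worst.distance_m) == (30, 210, 5.0)
        assert worst.n_pixels == 35_648

    def test_single_record_table_returns_it(self):
        import pandas as pd

        table = ArrangementTable(
            pd.DataFrame(
                [{"alpha_deg": 20, "height_cm": 220, "distance_m": 4.5,
                  "n_pixels": 56_985}]
            )
        )
        best = recommend_arrangement(table)
        assert best.n_pixels == 56_985

    def test_unsatisfiable_constraints_raise(self, table1):
        with pytest.raises(ValueError):
            recommend_arrangement(table1, min_distance_m=99.0)


class TestArrangementTableIO:
    def test_csv_round_trip(self, tmp_path):
        table = sweep_arrangements([20, 40], [220], [3.0, 4.0])
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = ArrangementTable.from_csv(path)
        np.testing.assert_allclose(
            back.records["n_pixels"], table.records["n_pixels"]
        )

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            ArrangementTable(pd.DataFrame({"alpha_deg": [10]}))
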