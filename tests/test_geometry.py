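"""Annular geometry: spline, plane, area, axes, dimensions, NPA."""

import numpy as np
import pytest

from annulokin.geometry import (
    AnnulusFrame,
    DegeneracyWarning,
    DegenerateGeometryError,
    GeometryError,
    SelfIntersectionWarning,
    analyze_frame,
    analyze_trajectory,
    axis_intersections,
    compute_dimensions_and_aci,
    compute_npa,
    fit_closed_spline,
    fit_plane_and_project,
    geometry_table,
    juncture_point,
    principal_axes,
    spline_area,
)
from annulokin.simulate import npa_closed_form

from conftest import ellipse_ring, random_rotation


class TestAnnulusFrame:
    def test_requires_exactly_eight_points(self):
        with pytest.raises(GeometryError, match="8 points"):
            AnnulusFrame(points=np.zeros((7, 3)))

    def test_rejects_coincident_consecutive_points(self):
        pts = ellipse_ring()
        pts[3] = pts[2] + 1e-4
        with pytest.raises(GeometryError, match="coincident"):
            AnnulusFrame(points=pts)

    def test_circular_adjacency_checked_across_seam(self):
        pts = ellipse_ring()
        pts[7] = pts[0] + 1e-4  # last adjacent to first
        with pytest.raises(GeometryError, match="coincident"):
            AnnulusFrame(points=pts)


class TestClosedSpline:
    def test_circle_oracle_curve_within_tolerance(self, circle_frame):
        sp = fit_closed_spline(circle_frame)
        radii = np.linalg.norm(sp.samples[:, :2], axis=1)
        assert np.abs(radii - 10.0).max() < 0.05
        assert np.abs(sp.samples[:, 2]).max() < 1e-12

    def test_knots_interpolated_exactly(self, saddle_frame):
        sp = fit_closed_spline(saddle_frame)
        recon = sp.spline(sp.knot_sites)
        assert np.abs(recon - saddle_frame.points).max() < 1e-9

    def test_periodic_seam_position_and_tangent(self, saddle_frame):
        sp = fit_closed_spline(saddle_frame)
        assert np.abs(sp.spline(0.0) - sp.spline(1.0)).max() < 1e-9
        assert np.abs(sp.spline(0.0, nu=1) - sp.spline(1.0, nu=1)).max() < 1e-9

    def test_too_few_samples_rejected(self, circle_frame):
        with pytest.raises(GeometryError, match="n_samples"):
            fit_closed_spline(circle_frame, n_samples=32)


class TestPlaneFit:
    def test_planar_ring_residuals_zero(self, ellipse_frame):
        sp = fit_closed_spline(ellipse_frame)
        plane, curve2d = fit_plane_and_project(sp)
        assert np.abs(plane.normal - [0, 0, 1]).max() < 1e-9
        resid = (sp.samples - plane.centroid) @ plane.normal
        assert np.abs(resid).max() < 1e-9

    def test_saddle_plane_is_symmetry_plane(self, saddle_frame):
        sp = fit_closed_spline(saddle_frame)
        plane, _ = fit_plane_and_project(sp)
        assert abs(abs(plane.normal[2]) - 1.0) < 1e-9
        # residual RMS ~ h/sqrt(2) for z = h cos(2 theta)
        resid = (sp.samples - plane.centroid) @ plane.normal
        assert np.sqrt(np.mean(resid**2)) == pytest.approx(2.0 / np.sqrt(2), rel=0.05)

    def test_rigid_rotation_rotates_normal_and_keeps_residuals(self, saddle_frame, rng):
        sp0 = fit_closed_spline(saddle_frame)
        _, curve0 = fit_plane_and_project(sp0)
        r0 = np.sort(np.abs((sp0.samples - sp0.samples.mean(0)) @ [0, 0, 1]))
        R = random_rotation(rng)
        frame = AnnulusFrame(points=saddle_frame.points @ R.T + [5.0, -3.0, 7.0])
        sp = fit_closed_spline(frame)
        plane, _ = fit_plane_and_project(sp)
        assert abs(abs(plane.normal @ (R @ [0, 0, 1])) - 1.0) < 1e-9
        resid = np.sort(np.abs((sp.samples - plane.centroid) @ plane.normal))
        assert np.abs(resid - r0).max() < 1e-9

    def test_collinear_samples_rejected(self):
        class FakeSpline:
            samples = np.column_stack([np.linspace(0, 1, 100), np.zeros(100), np.zeros(100)])

        with pytest.raises(DegenerateGeometryError, match="collinear"):
            fit_plane_and_project(FakeSpline())


class TestSplineArea:
    def test_circle_area(self, circle_frame):
        sp = fit_closed_spline(circle_frame)
        _, curve2d = fit_plane_and_project(sp)
        area, flag = spline_area(curve2d)
        assert area == pytest.approx(np.pi * 100.0, rel=0.005)
        assert not flag

    def test_ellipse_area(self, ellipse_frame):
        sp = fit_closed_spline(ellipse_frame)
        _, curve2d = fit_plane_and_project(sp)
        area, _ = spline_area(curve2d)
        assert area == pytest.approx(np.pi * 16.0 * 11.2, rel=0.01)

    def test_degenerate_flat_curve_zero_area(self):
        import warnings as _warnings

        t = np.linspace(0, 1, 50)
        seg = np.column_stack([np.r_[t, t[::-1]], np.zeros(100)])
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", SelfIntersectionWarning)
            area, _ = spline_area(seg)
        assert area == pytest.approx(0.0, abs=1e-12)

    def test_self_intersection_flagged_not_fatal(self):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        fig8 = np.column_stack([np.sin(2 * t), np.sin(t)])
        with pytest.warns(SelfIntersectionWarning):
            area, flag = spline_area(fig8)
        assert flag
        assert area >= 0.0


class TestPrincipalAxes:
    def test_axis_aligned_ellipse(self, ellipse_frame):
        sp = fit_closed_spline(ellipse_frame)
        _, curve2d = fit_plane_and_project(sp)
        axes = principal_axes(curve2d)
        assert abs(abs(axes.axis1[0]) - 1.0) < 1e-6
        assert not axes.degenerate

    def test_rotated_ellipse_axis_recovered(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        pts = np.column_stack([16 * np.cos(th), 11.2 * np.sin(th)])
        rot = np.radians(30.0)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        axes = principal_axes(pts @ R.T)
        ang = np.degrees(np.arctan2(axes.axis1[1], axes.axis1[0])) % 180.0
        assert ang == pytest.approx(30.0, abs=0.1)

    def test_circle_degeneracy_flag_and_orthonormality(self, circle_frame):
        sp = fit_closed_spline(circle_frame)
        _, curve2d = fit_plane_and_project(sp)
        with pytest.warns(DegeneracyWarning):
            axes = principal_axes(curve2d)
        assert axes.degenerate
        assert abs(axes.axis1 @ axes.axis2) < 1e-12
        assert np.linalg.norm(axes.axis1) == pytest.approx(1.0)

    def test_deterministic_sign_convention(self, ellipse_frame):
        sp = fit_closed_spline(ellipse_frame)
        _, curve2d = fit_plane_and_project(sp)
        axes = principal_axes(curve2d)
        assert axes.axis1[0] >= 0.0
        assert axes.axis2[0] >= 0.0 or (axes.axis2[0] == 0.0 and axes.axis2[1] >= 0.0)


class TestIntersectionsAndDimensions:
    def test_ellipse_major_axis_endpoints(self, ellipse_frame):
        sp = fit_closed_spline(ellipse_frame)
        plane, curve2d = fit_plane_and_project(sp)
        axes = principal_axes(curve2d)
        p_plus, p_minus = axis_intersections(sp, plane, axes.axis1)
        assert np.abs(np.abs(p_plus[0]) - 16.0) < 1e-6
        assert np.abs(p_plus[1]) < 1e-6
        assert np.abs(p_plus + p_minus).max() < 1e-6  # symmetric about centre

    def test_saddle_horns_on_minor_axis(self, saddle_frame):
        sp = fit_closed_spline(saddle_frame)
        plane, curve2d = fit_plane_and_project(sp)
        axes = principal_axes(curve2d)
        ah, ph = axis_intersections(sp, plane, axes.axis2)
        for p in (ah, ph):
            assert abs(abs(p[1]) - 11.2) < 1e-6
            assert p[2] == pytest.approx(2.0, abs=1e-6)  # both horns high

    def test_dimensions_and_aci(self, ellipse_frame):
        sp = fit_closed_spline(ellipse_frame)
        plane, curve2d = fit_plane_and_project(sp)
        axes = principal_axes(curve2d)
        icw, sl, aci, _ = compute_dimensions_and_aci(sp, plane, axes)
        assert icw == pytest.approx(32.0, abs=1e-6)
        assert sl == pytest.approx(22.4, abs=1e-6)
        assert aci == pytest.approx(0.700, abs=1e-6)

    def test_saddle_sl_unchanged_by_height(self, saddle_frame):
        sp = fit_closed_spline(saddle_frame)
        plane, curve2d = fit_plane_and_project(sp)
        axes = principal_axes(curve2d)
        _, sl, _, _ = compute_dimensions_and_aci(sp, plane, axes)
        assert sl == pytest.approx(22.4, abs=1e-3)  # horns at equal height


class TestNPA:
    def test_planar_annulus_flat_limit(self):
        npa = compute_npa(np.array([0, 11.2, 0.0]), np.array([0, -11.2, 0.0]), np.zeros(3))
        assert npa == pytest.approx(180.0, abs=1e-9)

    def test_saddle_closed_form(self):
        npa = compute_npa(np.array([0, 11.2, 2.0]), np.array([0, -11.2, 2.0]), np.zeros(3))
        assert npa == pytest.approx(npa_closed_form(11.2, 2.0), abs=1e-9)
        assert npa == pytest.approx(159.75, abs=0.01)

    def test_zero_length_vector_rejected(self):
        with pytest.raises(GeometryError, match="juncture"):
            compute_npa(np.zeros(3), np.array([0, 1.0, 0]), np.zeros(3))

    def test_juncture_of_skew_axis_lines(self):
        # horns at z=+h, commissures at z=-h: juncture midway at z=0
        j = juncture_point(
            np.array([0, 11.2, 2.0]),
            np.array([0, -11.2, 2.0]),
            np.array([16.0, 0, -2.0]),
            np.array([-16.0, 0, -2.0]),
        )
        assert np.abs(j).max() < 1e-12


class TestAnalyzeFrame:
    def test_saddle_ellipse_composite_metrics(self, saddle_frame):
        gf = analyze_frame(saddle_frame)
        assert gf.MAA == pytest.approx(np.pi * 16 * 11.2, rel=0.01)
        assert gf.ACI == pytest.approx(0.700, abs=0.005)
        assert gf.NPA == pytest.approx(159.75, abs=0.5)
        assert not gf.flag_degenerate and not gf.flag_selfintersect

    def test_rigid_motion_invariance(self, saddle_frame, rng):
        ref = analyze_frame(saddle_frame)
        for _ in range(20):
            R = random_rotation(rng)
            t = rng.normal(0, 50, 3)
            gf = analyze_frame(AnnulusFrame(points=saddle_frame.points @ R.T + t))
            for attr in ("MAA", "SL", "ICW", "ACI", "NPA"):
                assert getattr(gf, attr) == pytest.approx(getattr(ref, attr), rel=1e-6)

    def test_scale_equivariance(self, saddle_frame):
        ref = analyze_frame(saddle_frame)
        s = 2.5
        gf = analyze_frame(AnnulusFrame(points=s * saddle_frame.points))
        assert gf.MAA == pytest.approx(s**2 * ref.MAA, rel=1e-9)
        assert gf.SL == pytest.approx(s * ref.SL, rel=1e-9)
        assert gf.ICW == pytest.approx(s * ref.ICW, rel=1e-9)
        assert gf.ACI == pytest.approx(ref.ACI, rel=1e-9)
        assert gf.NPA == pytest.approx(ref.NPA, rel=1e-9)

    def test_stage_identified_in_errors(self):
        pts = ellipse_ring()
        frame = AnnulusFrame(points=pts)
        with pytest.raises(GeometryError, match=r"\[spline\]"):
            analyze_frame(frame, n_samples=8)

    def test_trajectory_table_layout(self, saddle_frame):
        coords = np.stack([saddle_frame.points] * 3)
        frames = analyze_trajectory([0.0, 0.00853, 0.01706], coords)
        tab = geometry_table(frames)
        assert list(tab.columns) == [
            "time_s",
            "MAA_mm2",
            "SL_mm",
            "ICW_mm",
            "ACI",
            "NPA_deg",
            "flag_degenerate",
            "flag_selfintersect",
        ]
        assert len(tab) == 3
        assert tab["MAA_mm2"].std() < 1e-9
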