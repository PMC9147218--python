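"""Unit and property tests for the 2D fluoroscopic measurement method."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cuporient import fluoro2d as f2
from cuporient.geometry3d import CupPose
from cuporient.simulator import NoiseModel, simulate_radiograph_pair

from conftest import rim_projection_oracle


def ellipse_points(a, b, theta_deg, center=(0.0, 0.0), n=12, t0=0.0):
    t = t0 + np.linspace(0, 2 * np.pi, n, endpoint=False)
    th = np.radians(theta_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return np.column_stack([a * np.cos(t), b * np.sin(t)]) @ R.T + np.asarray(center)


class TestFitEllipse:
    def test_circle_limit(self):
        e = f2.fit_ellipse(ellipse_points(10, 10, 0, n=8))
        assert abs(e.semi_major - 10) < 1e-9
        assert abs(e.semi_minor - 10) < 1e-9

    def test_exact_ellipse_recovered(self):
        e = f2.fit_ellipse(ellipse_points(27, 7, 30, center=(3, -5)))
        assert abs(e.semi_major - 27) < 27 * 1e-9
        assert abs(e.semi_minor - 7) < 7 * 1e-9
        assert abs(e.major_axis_angle - 30) < 1e-9
        np.testing.assert_allclose(e.center, (3, -5), atol=1e-8)

    def test_five_points_match_direct_linear_solve(self, rng):
        """With exactly 5 points the constrained fit reduces to the unique
        conic through them (computed independently as an SVD nullspace)."""
        pts = ellipse_points(20, 9, 40, center=(4, 2), n=5, t0=0.3)
        e = f2.fit_ellipse(pts)
        x, y = pts[:, 0], pts[:, 1]
        A = np.column_stack([x * x, x * y, y * y, x, y, np.ones(5)])
        _, _, vt = np.linalg.svd(A)
        conic = vt[-1]
        # the unique conic must vanish on fitted-ellipse points
        probe = ellipse_points(e.semi_major, e.semi_minor, e.major_axis_angle,
                               center=e.center, n=16, t0=0.1)
        vals = (conic[0] * probe[:, 0] ** 2 + conic[1] * probe[:, 0] * probe[:, 1]
                + conic[2] * probe[:, 1] ** 2 + conic[3] * probe[:, 0]
                + conic[4] * probe[:, 1] + conic[5])
        assert np.max(np.abs(vals)) < 1e-6 * np.max(np.abs(conic))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            f2.fit_ellipse(ellipse_points(10, 5, 0, n=4))

    def test_degenerate_conic_data_rejected(self):
        """Collinear points admit no ellipse; the constrained fit must refuse
        rather than return a degenerate conic."""
        x = np.linspace(-5, 5, 8)
        collinear = np.column_stack([x, 2.0 * x + 1.0])
        with pytest.raises(f2.NonEllipticalInputError):
            f2.fit_ellipse(collinear)


class TestReferenceAxis:
    def test_teardrop_angle_examples(self):
        lm = f2.Landmarks2D(teardrop_pair=np.array([[0.0, 0.0], [100.0, 0.0]]))
        assert f2.ml_axis_from_teardrops(lm) == 0.0
        lm45 = f2.Landmarks2D(teardrop_pair=np.array([[0.0, 0.0], [100.0, 100.0]]))
        assert abs(f2.ml_axis_from_teardrops(lm45) - 45.0) < 1e-12

    def test_teardrop_angle_is_a_line_not_a_vector(self):
        a = f2.Landmarks2D(teardrop_pair=np.array([[0.0, 0.0], [100.0, 30.0]]))
        b = f2.Landmarks2D(teardrop_pair=np.array([[100.0, 30.0], [0.0, 0.0]]))
        assert abs(f2.ml_axis_from_teardrops(a) - f2.ml_axis_from_teardrops(b)) < 1e-12

    def test_coincident_teardrops_rejected(self):
        lm = f2.Landmarks2D(teardrop_pair=np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(Exception):
            f2.ml_axis_from_teardrops(lm)

    @staticmethod
    def _views(teardrop_angle, brim1_angle, brim2_angle):
        def seg(angle):
            a = np.radians(angle)
            return np.array([[0.0, 0.0], [np.cos(a), np.sin(a)]]) * 60.0
        full = f2.Landmarks2D(teardrop_pair=seg(teardrop_angle),
                              brim_line=seg(brim1_angle))
        cup = f2.Landmarks2D(brim_line=seg(brim2_angle))
        return full, cup

    def test_identity_transfer(self):
        full, cup = self._views(10.0, 37.0, 37.0)
        assert abs(f2.transfer_ml_axis(full, cup) - 10.0) < 1e-9

    def test_rotated_view_transfer(self):
        full, cup = self._views(10.0, 37.0, 37.0 + 25.0)
        assert abs(f2.transfer_ml_axis(full, cup) - 35.0) < 1e-9

    def test_angle_arithmetic_example(self):
        full, cup = self._views(0.0, 37.0, 52.0)
        assert abs(f2.transfer_ml_axis(full, cup) - 15.0) < 1e-9


class TestRadiographicAngles:
    def test_circle_is_face_on(self):
        e = f2.Ellipse2D(center=(0, 0), semi_major=10, semi_minor=10,
                         major_axis_angle=0.0)
        r = f2.radiographic_angles(e, ml_axis_angle=12.0)
        assert r.ra == 90.0 and r.ri == 0.0 and r.circular

    def test_segment_is_edge_on(self):
        e = f2.Ellipse2D(center=(0, 0), semi_major=10, semi_minor=0.0,
                         major_axis_angle=50.0)
        r = f2.radiographic_angles(e, ml_axis_angle=0.0)
        assert r.ra == 0.0
        assert abs(r.ri - 50.0) < 1e-12

    def test_matches_forward_projection_oracle(self):
        """Fitted ellipse of a projected rim at (40, 15) reproduces the
        brute-force cloud's RI = 39.03 and RA = 9.58 degrees."""
        ri_o, ra_o, a_o, b_o = rim_projection_oracle(40.0, 15.0)
        assert abs(ri_o - 39.03) < 0.006
        assert abs(ra_o - 9.58) < 0.006
        assert abs(b_o - 4.492) < 0.001
        e = f2.Ellipse2D(center=(0, 0), semi_major=a_o, semi_minor=b_o,
                         major_axis_angle=180.0 - ri_o)  # major axis left-leaning
        r = f2.radiographic_angles(e, ml_axis_angle=0.0)
        assert abs(r.ri - ri_o) < 1e-9
        assert abs(r.ra - ra_o) < 1e-9


class TestAnatomicFromRadiographic:
    def test_zero_anteversion_limit(self):
        est = f2.anatomic_from_radiographic(f2.RadiographicAngles(35.0, 0.0, False))
        assert abs(est.inclination - 35.0) < 1e-12
        assert est.anteversion == 0.0

    def test_vertical_cup_limit(self):
        est = f2.anatomic_from_radiographic(f2.RadiographicAngles(90.0, 17.0, False))
        assert abs(est.inclination - 90.0) < 1e-9
        assert abs(est.anteversion - 17.0) < 1e-9

    def test_inverse_of_projection_at_grid_point(self):
        ri, ra, _, _ = rim_projection_oracle(40.0, 15.0)
        est = f2.anatomic_from_radiographic(f2.RadiographicAngles(ri, ra, False))
        assert abs(est.inclination - 40.0) < 1e-6
        assert abs(est.anteversion - 15.0) < 1e-6

    def test_inconsistent_measurement_rejected(self):
        with pytest.raises(f2.InconsistentMeasurementError):
            f2.anatomic_from_radiographic(f2.RadiographicAngles(0.01, 20.0, False))

    def test_double_degenerate_flagged(self):
        est = f2.anatomic_from_radiographic(f2.RadiographicAngles(0.0, 0.0, False))
        assert est == (0.0, 0.0, True)

    @given(st.floats(5.0, 85.0), st.floats(5.0, 85.0))
    def test_round_trip_against_forward_formulas(self, ai, av):
        """anatomic -> radiographic (closed form) -> anatomic is the identity."""
        i, v = np.radians(ai), np.radians(av)
        ri = np.degrees(np.arctan(np.tan(i) * np.cos(v)))
        ra = np.degrees(np.arcsin(np.sin(i) * np.sin(v)))
        est = f2.anatomic_from_radiographic(f2.RadiographicAngles(ri, ra, False))
        assert abs(est.inclination - ai) < 1e-9
        assert abs(est.anteversion - av) < 1e-9

    def test_monotonicity_in_anteversion(self):
        """RA strictly increases and RI strictly decreases with anteversion."""
        for ai in (20.0, 45.0, 70.0):
            i = np.radians(ai)
            av = np.radians(np.arange(1.0, 90.0, 1.0))
            ra = np.degrees(np.arcsin(np.sin(i) * np.sin(av)))
            ri = np.degrees(np.arctan(np.tan(i) * np.cos(av)))
            assert np.all(np.diff(ra) > 0)
            assert np.all(np.diff(ri) < 0)


def noiseless_pair(inclination, anteversion, seed=0):
    pose = CupPose(inclination, anteversion, 27.0, np.array([65.0, 0.0, 10.0]))
    noise = NoiseModel(rim_sigma=0.0, landmark_sigma=0.0, arc_fraction=1.0)
    pair, _ = simulate_radiograph_pair(pose, noise=noise, seed=seed)
    return pair


def rotate_landmarks(lm: f2.Landmarks2D, angle_deg: float) -> f2.Landmarks2D:
    t = np.radians(angle_deg)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])

    def rot(a):
        return None if a is None else np.asarray(a, float) @ R.T

    return f2.Landmarks2D(teardrop_pair=rot(lm.teardrop_pair),
                          brim_line=rot(lm.brim_line),
                          rim_points=rot(lm.rim_points))


class TestMeasureCup:
    @pytest.mark.parametrize("inclination", [20.0, 40.0, 60.0])
    @pytest.mark.parametrize("anteversion", [10.0, 25.0, 40.0])
    def test_noiseless_recovery_on_study_grid(self, inclination, anteversion):
        m = f2.measure_cup(noiseless_pair(inclination, anteversion))
        assert abs(m.pose.inclination - inclination) < 1e-6
        assert abs(m.pose.anteversion - anteversion) < 1e-6
        assert abs(m.pose.rim_radius - 27.0) < 1e-6

    def test_in_plane_rotation_invariance(self):
        pair = noiseless_pair(40.0, 15.0)
        m0 = f2.measure_cup(pair)
        rotated = f2.RadiographPair(
            full_pelvis=rotate_landmarks(pair.full_pelvis, 25.0),
            cup_view=rotate_landmarks(pair.cup_view, 25.0),
        )
        m1 = f2.measure_cup(rotated)
        assert abs(m1.pose.inclination - m0.pose.inclination) < 1e-9
        assert abs(m1.pose.anteversion - m0.pose.anteversion) < 1e-9

    def test_cup_view_rotation_alone_is_invariant(self):
        """Rotating only the cup view (with its brim line) changes nothing:
        the brim transfer carries the reference axis along."""
        pair = noiseless_pair(40.0, 15.0)
        m0 = f2.measure_cup(pair)
        rotated = f2.RadiographPair(
            full_pelvis=pair.full_pelvis,
            cup_view=rotate_landmarks(pair.cup_view, -33.0),
        )
        m1 = f2.measure_cup(rotated)
        assert abs(m1.pose.inclination - m0.pose.inclination) < 1e-9
        assert abs(m1.pose.anteversion - m0.pose.anteversion) < 1e-9

    def test_retroversion_is_folded_and_flagged(self):
        """A negated anterior tilt projects to the identical ellipse; the
        non-negative branch is reported, with the ambiguity flag set."""
        m = f2.measure_cup(noiseless_pair(40.0, 15.0))
        assert "retroversion_ambiguous" in m.flags
        assert m.pose.anteversion >= 0

    def test_file_round_trip(self, tmp_path):
        pair = noiseless_pair(40.0, 15.0)
        path = tmp_path / "pair.csv"
        f2.write_landmarks_2d(path, pair)
        full, cup = f2.read_landmarks_2d(path)
        m0 = f2.measure_cup(pair)
        m1 = f2.measure_cup(f2.RadiographPair(full_pelvis=full, cup_view=cup))
        assert abs(m0.pose.inclination - m1.pose.inclination) < 1e-4
        assert abs(m0.pose.anteversion - m1.pose.anteversion) < 1e-4

    def test_missing_rim_points_rejected(self):
        pair = noiseless_pair(40.0, 15.0)
        with pytest.raises(ValueError, match="rim points"):
            f2.RadiographPair(
                full_pelvis=pair.full_pelvis,
                cup_view=f2.Landmarks2D(brim_line=pair.cup_view.brim_line),
            )
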