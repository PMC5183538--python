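"""Path length, wrapping, moment arms, and subject scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from elbowext.errors import GeometryError, ValidationError
from elbowext.geometry import (MusclePath, PathPoint, WrapObject, moment_arm,
                               musculotendon_length, scale_geometry,
                               wrap_segment)

MUSCLES = ("MHT", "LatHT", "LngHT")


def hinge_path(origin_xy, insertion_xy, wraps=()):
    return MusclePath(
        muscle_id="toy",
        origin=PathPoint(np.array([*origin_xy, 0.0])),
        insertion=PathPoint(np.array([*insertion_xy, 0.0]), segment="ulna"),
        wraps=tuple(wraps),
    )


class TestMusculotendonLength:
    def test_two_point_humerus_fixed_is_euclidean(self, two_point_path):
        for theta in (0.0, 45.0, 130.0):
            assert musculotendon_length(two_point_path, theta) == pytest.approx(5.0)

    def test_two_point_closed_form_over_hinge(self):
        # origin on the humerus, insertion on the ulna at radius r:
        # law of cosines in the hinge plane
        a, r = 10.0, 2.0
        path = hinge_path((0.0, a), (0.0, -r))
        for theta in (0.0, 30.0, 90.0, 130.0):
            th = math.radians(theta)
            expected = math.sqrt(a * a + r * r - 2 * a * r * math.cos(math.pi - th))
            assert musculotendon_length(path, theta) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_angle_rejected(self, two_point_path):
        with pytest.raises(ValidationError):
            musculotendon_length(two_point_path, 131.0)
        with pytest.raises(ValidationError):
            musculotendon_length(two_point_path, -1.0)

    def test_coincident_points_rejected(self):
        path = MusclePath(
            muscle_id="bad",
            origin=PathPoint(np.array([1.0, 1.0, 0.0])),
            insertion=PathPoint(np.array([1.0, 1.0, 0.0])),
        )
        with pytest.raises(GeometryError):
            musculotendon_length(path, 10.0)

    def test_default_geometry_continuous(self, default_geometry):
        # the modeled paths must have no length jumps anywhere in the range
        thetas = np.arange(0.0, 130.01, 0.25)
        for mid in MUSCLES:
            ls = np.array([musculotendon_length(default_geometry.paths[mid], t)
                           for t in thetas])
            steps = np.abs(np.diff(ls))
            assert steps.max() < 0.02  # cm per 0.25 degrees

    def test_long_head_excursion_21_percent(self, default_geometry):
        p = default_geometry.paths["LngHT"]
        l0 = musculotendon_length(p, 0.0)
        l130 = musculotendon_length(p, 130.0)
        assert 100.0 * (l130 - l0) / l0 == pytest.approx(21.0, abs=1.0)


class TestWrapSegment:
    def test_clear_segment_unchanged(self):
        w = WrapObject("sphere", center=[0.0, 0.0, 0.0], radius=1.0)
        verts, length = wrap_segment([5.0, 5.0, 0.0], [6.0, 5.0, 0.0], w)
        assert len(verts) == 2
        assert length == pytest.approx(1.0)

    def test_endpoint_inside_rejected(self):
        w = WrapObject("sphere", center=[0.0, 0.0, 0.0], radius=2.0)
        with pytest.raises(GeometryError):
            wrap_segment([0.5, 0.0, 0.0], [5.0, 0.0, 0.0], w)

    def test_sphere_diametric_closed_form(self):
        # endpoints at 2R on opposite sides, chord through the center:
        # two tangents of length R*sqrt(3) plus a 60-degree great-circle arc
        R = 1.5
        w = WrapObject("sphere", center=[0.0, 0.0, 0.0], radius=R)
        _, length = wrap_segment([2 * R, 0.0, 0.0], [-2 * R, 0.0, 0.0], w)
        assert length == pytest.approx(2 * math.sqrt(3) * R + math.pi * R / 3, rel=1e-9)

    def test_sphere_against_numeric_shortest_path(self):
        # independent oracle: minimize leg+arc+leg over the two touch
        # angles, with a barrier against legs cutting through the sphere
        R = 1.0
        p = np.array([3.0, 0.4])
        q = np.array([-2.0, -0.6])

        def seg_dist(a, b):
            d = b - a
            t = np.clip(-(a @ d) / (d @ d), 0.0, 1.0)
            return np.linalg.norm(a + t * d)

        def total(phis):
            t1 = R * np.array([math.cos(phis[0]), math.sin(phis[0])])
            t2 = R * np.array([math.cos(phis[1]), math.sin(phis[1])])
            arc = abs((phis[1] - phis[0] + math.pi) % (2 * math.pi) - math.pi)
            length = np.linalg.norm(t1 - p) + R * arc + np.linalg.norm(q - t2)
            penalty = sum(
                1e3 * (R - dd) ** 2
                for dd in (seg_dist(p, t1), seg_dist(t2, q))
                if dd < R - 1e-9
            )
            return length + penalty

        best = min(
            minimize(total, x0, method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000}).fun
            for x0 in ([0.5, 2.5], [-0.5, -2.5], [0.2, -2.9])
        )
        w = WrapObject("sphere", center=[0.0, 0.0, 0.0], radius=R)
        _, length = wrap_segment([*p, 0.0], [*q, 0.0], w)
        assert length == pytest.approx(best, abs=1e-6)

    def test_cylinder_matches_planar_tangent_construction(self):
        # all points in a plane normal to the axis: 2-D circle tangent formula
        R = 1.2
        w = WrapObject("cylinder", center=[0.0, 0.0, 0.0], axis=[0.0, 0.0, 1.0], radius=R)
        p, q = np.array([4.0, 0.5]), np.array([-3.0, -0.8])
        _, length = wrap_segment([*p, 0.0], [*q, 0.0], w)
        lp = math.sqrt(p @ p - R * R)
        lq = math.sqrt(q @ q - R * R)
        ang = math.acos((p @ q) / (np.linalg.norm(p) * np.linalg.norm(q)))
        arc = ang - math.acos(R / np.linalg.norm(p)) - math.acos(R / np.linalg.norm(q))
        assert length == pytest.approx(lp + R * arc + lq, rel=1e-9)

    def test_cylinder_helical_length(self):
        # out-of-plane endpoints: unrolled development is a right triangle
        R = 1.0
        w = WrapObject("cylinder", center=[0.0, 0.0, 0.0], axis=[0.0, 0.0, 1.0], radius=R)
        _, planar = wrap_segment([3.0, 0.2, 0.0], [-3.0, -0.2, 0.0], w)
        dz = 2.0
        _, helical = wrap_segment([3.0, 0.2, 0.0], [-3.0, -0.2, dz], w)
        assert helical == pytest.approx(math.hypot(planar, dz), rel=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(
        px=st.floats(2.1, 6.0), py=st.floats(-4.0, 4.0),
        qx=st.floats(-6.0, -2.1), qy=st.floats(-4.0, 4.0),
        qz=st.floats(-2.0, 2.0),
    )
    def test_wrapped_length_never_below_chord(self, px, py, qx, qy, qz):
        w = WrapObject("cylinder", center=[0.0, 0.0, 0.0], axis=[0.0, 0.0, 1.0], radius=2.0)
        p, q = np.array([px, py, 0.0]), np.array([qx, qy, qz])
        _, length = wrap_segment(p, q, w)
        assert length >= np.linalg.norm(q - p) - 1e-9


class TestMomentArm:
    def test_pure_lever_perpendicular_configuration(self):
        # insertion at radius 2 on the ulna; at the angle where the path is
        # perpendicular to the lever the moment arm equals the radius
        path = hinge_path((10.0, 0.0), (0.0, -2.0))
        theta = math.degrees(math.asin(0.2))  # sin(theta) = r/a
        # magnitude equals the lever radius (sign: this toy muscle flexes)
        assert abs(moment_arm(path, theta, step=0.01)) == pytest.approx(2.0, abs=1e-6)

    def test_matches_analytic_lever_formula(self):
        # closed form for a single straight segment over the hinge
        a, r = 10.0, 2.0
        path = hinge_path((0.0, a), (0.0, -r))
        for theta in (15.0, 45.0, 80.0, 120.0):
            th = math.radians(theta)
            l = math.sqrt(a * a + r * r + 2 * a * r * math.cos(th))
            expected = -a * r * math.sin(th) / l  # shortens with flexion: flexor
            assert moment_arm(path, theta, step=0.01) == pytest.approx(expected, abs=1e-6)

    def test_humerus_fixed_path_has_zero_moment_arm(self, two_point_path):
        for theta in (10.0, 65.0, 120.0):
            assert moment_arm(two_point_path, theta) == pytest.approx(0.0, abs=1e-12)

    def test_one_sided_difference_at_boundaries(self, default_geometry):
        p = default_geometry.paths["LngHT"]
        assert moment_arm(p, 0.0) == pytest.approx(1.81, abs=1e-9)
        assert moment_arm(p, 130.0) == pytest.approx(1.81, abs=1e-9)

    def test_nonpositive_step_rejected(self, two_point_path):
        with pytest.raises(ValidationError):
            moment_arm(two_point_path, 50.0, step=0.0)

    @pytest.mark.parametrize("mid,target", [("MHT", 1.70), ("LatHT", 1.71), ("LngHT", 1.81)])
    def test_default_geometry_mean_moment_arms(self, default_geometry, mid, target):
        mas = [moment_arm(default_geometry.paths[mid], float(t)) for t in range(131)]
        assert np.mean(mas) == pytest.approx(target, abs=0.02)

    def test_extension_moment_arm_positive_for_extensors(self, default_geometry):
        for mid in MUSCLES:
            assert moment_arm(default_geometry.paths[mid], 60.0) > 0


class TestScaling:
    def test_identity(self, default_geometry):
        paths = scale_geometry(default_geometry, default_geometry.reference_upper_arm,
                               default_geometry.reference_forearm)
        for mid in MUSCLES:
            for theta in (0.0, 60.0, 130.0):
                assert musculotendon_length(paths[mid], theta) == pytest.approx(
                    musculotendon_length(default_geometry.paths[mid], theta))

    @settings(derandomize=True, max_examples=20)
    @given(s=st.floats(0.5, 2.0))
    def test_uniform_scaling_homogeneity(self, default_geometry, s):
        paths = scale_geometry(default_geometry, s * default_geometry.reference_upper_arm,
                               s * default_geometry.reference_forearm)
        p0 = default_geometry.paths["LngHT"]
        for theta in (0.0, 45.0, 100.0):
            assert musculotendon_length(paths["LngHT"], theta) == pytest.approx(
                s * musculotendon_length(p0, theta), rel=1e-9)
        assert moment_arm(paths["LngHT"], 60.0) == pytest.approx(
            s * moment_arm(p0, 60.0), rel=1e-6)

    def test_anisotropic_scaling_against_hand_scaled_coordinates(self, default_geometry):
        su, sf = 1.1, 0.9
        scaled = scale_geometry(default_geometry,
                                su * default_geometry.reference_upper_arm,
                                sf * default_geometry.reference_forearm)
        # independent re-evaluation from hand-scaled coordinates
        src = default_geometry.paths["MHT"]
        hand = MusclePath(
            muscle_id="MHT",
            origin=PathPoint(src.origin.xyz * su),
            insertion=PathPoint(src.insertion.xyz * sf, segment="ulna"),
            wraps=tuple(
                WrapObject(w.kind, w.center * su, w.radius * su, w.axis,
                           w.active_range, w.side)
                for w in src.wraps
            ),
        )
        assert musculotendon_length(scaled["MHT"], 90.0) == pytest.approx(
            musculotendon_length(hand, 90.0), rel=1e-12)

    def test_nonpositive_lengths_rejected(self, default_geometry):
        with pytest.raises(ValidationError):
            scale_geometry(default_geometry, 0.0, 25.0)
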