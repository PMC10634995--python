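import math

import numpy as np
import pytest

from lrrwind import (
    NumericalError,
    PlanarCurve,
    SolenoidSpec,
    gaussian_derivative_kernel,
    make_solenoid,
    parallel_transport_frames,
    project_normal_bundle,
    smooth_core,
    tangent_field,
    winding_number,
)
from lrrwind.geometry import CoreCurve, derivative_filter

from conftest import unwrapped_angle_winding


class TestGaussianDerivativeKernel:
    def test_zero_at_center(self):
        for sigma in (0.5, 1.0, 3.0):
            kernel = gaussian_derivative_kernel(sigma)
            assert kernel[len(kernel) // 2] == 0.0

    def test_value_at_unit_offset_sigma_one(self):
        kernel = gaussian_derivative_kernel(1.0)
        j1 = kernel[len(kernel) // 2 + 1]
        assert j1 == pytest.approx(-(1.0 / (2.0 * math.pi)) * math.exp(-0.5), rel=1e-12)

    def test_antisymmetric_and_zero_sum(self):
        kernel = gaussian_derivative_kernel(2.0, radius=10)
        assert np.allclose(kernel, -kernel[::-1])
        assert np.sum(kernel) == pytest.approx(0.0, abs=1e-15)

    def test_radius_below_support_rejected(self):
        with pytest.raises(ValueError):
            gaussian_derivative_kernel(2.0, radius=3)
        with pytest.raises(ValueError):
            gaussian_derivative_kernel(-1.0)

    def test_filter_differentiates_ramps_exactly(self):
        ramp = 2.5 * np.arange(100) - 7.0
        deriv = derivative_filter(ramp, 1.0)
        np.testing.assert_allclose(deriv[8:-8], 2.5, atol=1e-10)


class TestSmoothCore:
    def test_constant_curve_unchanged(self):
        pts = np.tile([1.0, -2.0, 3.0], (60, 1))
        core = smooth_core(pts, 6.0)
        np.testing.assert_allclose(core.points, pts, atol=1e-12)

    def test_vanishing_bandwidth_is_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40, 3))
        core = smooth_core(pts, 1e-4)
        np.testing.assert_allclose(core.points, pts, atol=1e-12)

    def test_helix_shrinks_inside_its_radius(self):
        t = np.arange(200)
        pts = np.column_stack(
            [8 * np.cos(2 * np.pi * t / 24), 8 * np.sin(2 * np.pi * t / 24), 0.2 * t]
        )
        core = smooth_core(pts, 6.0)
        radius = np.linalg.norm(core.points[20:-20, :2], axis=1)
        assert np.all(radius < 8.0)
        # oracle: direct numerical convolution with the same normalized kernel
        j = np.arange(-24, 25)
        kernel = np.exp(-(j**2) / (2 * 6.0**2))
        kernel /= kernel.sum()
        # (scipy's "reflect" is half-sample symmetric == np.pad "symmetric")
        direct = np.convolve(np.pad(pts[:, 0], 24, mode="symmetric"), kernel, "valid")
        np.testing.assert_allclose(core.points[:, 0], direct, atol=1e-10)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_core(np.zeros((60, 3)), 0.0)


class TestTangentField:
    def test_straight_line_tangents(self):
        pts = np.column_stack([np.zeros(50), np.zeros(50), np.arange(50.0)])
        tangents = tangent_field(pts)
        np.testing.assert_allclose(tangents.vectors, [[0, 0, 1.0]] * 50, atol=1e-10)

    def test_circle_tangents_orthogonal_to_radius(self):
        t = np.arange(400)
        pts = np.column_stack(
            [np.cos(2 * np.pi * t / 400), np.sin(2 * np.pi * t / 400), np.zeros(400)]
        )
        tangents = tangent_field(pts)
        dots = np.einsum("ij,ij->i", tangents.vectors, pts)
        assert np.max(np.abs(dots[8:-8])) < 1e-3  # open-curve ends excluded

    def test_unit_norms(self):
        rng = np.random.default_rng(1)
        pts = np.cumsum(rng.normal(size=(80, 3)), axis=0)
        tangents = tangent_field(pts)
        np.testing.assert_allclose(
            np.linalg.norm(tangents.vectors, axis=1), 1.0, atol=1e-8
        )

    def test_stationary_curve_is_numerical_error(self):
        with pytest.raises(NumericalError, match="position"):
            tangent_field(np.tile([1.0, 1.0, 1.0], (50, 1)))


def _circle_core(n):
    t = np.arange(n)
    return np.column_stack(
        [np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n), np.zeros(n)]
    )


class TestParallelTransport:
    def test_constant_tangents_freeze_the_frame(self):
        from lrrwind.geometry import TangentField

        tangents = TangentField(np.tile([0.0, 0.0, 1.0], (30, 1)), 1.0)
        frames = parallel_transport_frames(tangents, seed=3)
        expected = np.tile(frames.frames[0], (30, 1, 1))
        np.testing.assert_allclose(frames.frames, expected, atol=1e-12)

    def test_orthonormality_invariants(self):
        rng = np.random.default_rng(2)
        pts = np.cumsum(rng.normal(size=(120, 3)) + [0.2, 0, 0.4], axis=0)
        tangents = tangent_field(smooth_core(pts, 3.0))
        frames = parallel_transport_frames(tangents, seed=0)
        u, v = frames.frames[:, 0, :], frames.frames[:, 1, :]
        assert np.max(np.abs(np.einsum("ij,ij->i", u, u) - 1)) < 1e-8
        assert np.max(np.abs(np.einsum("ij,ij->i", v, v) - 1)) < 1e-8
        assert np.max(np.abs(np.einsum("ij,ij->i", u, v))) < 1e-8
        assert np.max(np.abs(np.einsum("ij,ij->i", u, tangents.vectors))) < 1e-6
        assert np.max(np.abs(np.einsum("ij,ij->i", v, tangents.vectors))) < 1e-6

    def test_planar_circle_keeps_out_of_plane_component(self):
        coarse = tangent_field(_circle_core(100))
        frames = parallel_transport_frames(coarse, seed=5)
        uz = frames.frames[:, 0, 2]
        assert np.max(np.abs(uz - uz[0])) < 1e-4
        # oracle: the same transport at 10x finer sampling of the same circle
        fine = parallel_transport_frames(tangent_field(_circle_core(1000)), seed=5)
        assert np.max(np.abs(fine.frames[:, 0, 2] - fine.frames[0, 0, 2])) < 1e-4


class TestProjectNormalBundle:
    def test_zero_displacement(self):
        pts = np.cumsum(np.ones((60, 3)), axis=0)
        core = CoreCurve(pts.copy(), 1.0)
        frames = parallel_transport_frames(tangent_field(core), seed=0)
        planar = project_normal_bundle(pts, core, frames)
        np.testing.assert_allclose(planar.xy, 0.0, atol=1e-12)

    def test_unit_displacement_along_u(self):
        pts = np.column_stack([np.zeros(60), np.zeros(60), np.arange(60.0)])
        core = CoreCurve(pts.copy(), 1.0)
        frames = parallel_transport_frames(tangent_field(core), seed=1)
        displaced = pts + frames.frames[:, 0, :]
        planar = project_normal_bundle(displaced, core, frames)
        np.testing.assert_allclose(planar.xy[:, 0], 1.0, atol=1e-10)
        np.testing.assert_allclose(planar.xy[:, 1], 0.0, atol=1e-10)

    def test_helix_about_straight_axis_traces_circle(self):
        t = np.arange(241)
        helix = np.column_stack(
            [8 * np.cos(2 * np.pi * t / 24), 8 * np.sin(2 * np.pi * t / 24),
             0.2083 * t]
        )
        axis = np.column_stack([np.zeros(241), np.zeros(241), 0.2083 * t])
        core = CoreCurve(axis, 1.0)
        frames = parallel_transport_frames(tangent_field(core), seed=0)
        planar = project_normal_bundle(helix, core, frames)
        radius = np.linalg.norm(planar.xy, axis=1)
        np.testing.assert_allclose(radius, 8.0, atol=1e-6)

    def test_length_mismatch_rejected(self):
        pts = np.cumsum(np.ones((60, 3)), axis=0)
        core = CoreCurve(pts[:50], 1.0)
        frames = parallel_transport_frames(tangent_field(pts), seed=0)
        with pytest.raises(ValueError):
            project_normal_bundle(pts, core, frames)


class TestWindingNumber:
    def test_unit_circle_single_traversal(self):
        t = np.arange(200)
        xy = np.column_stack(
            [np.cos(2 * np.pi * t / 200), np.sin(2 * np.pi * t / 200)]
        )
        profile = winding_number(PlanarCurve(xy=xy))
        assert profile.w[0] == 0.0
        assert profile.w[-1] == pytest.approx(1.0, abs=0.02)

    def test_right_half_plane_curve_stays_below_half_turn(self):
        t = np.linspace(0, 2 * np.pi, 150)
        xy = np.column_stack([2.0 + 0.5 * np.cos(3 * t), np.sin(2 * t)])
        profile = winding_number(PlanarCurve(xy=xy))
        assert abs(profile.w[-1]) < 0.5

    def test_solenoid_projection_matches_turn_count_and_oracle(self):
        curve, _ = make_solenoid(SolenoidSpec(turns=8, period=24))
        core = smooth_core(curve, 12.0)
        frames = parallel_transport_frames(tangent_field(core), seed=0)
        planar = project_normal_bundle(curve, core, frames)
        profile = winding_number(planar)
        assert profile.w[-1] == pytest.approx(8.0, abs=0.25)
        oracle = np.abs(unwrapped_angle_winding(planar.xy))
        assert abs(profile.w[-1] - oracle[-1]) < 0.05
        assert np.max(np.abs(profile.w[8:-8] - oracle[8:-8])) < 0.05

    def test_monotone_on_ideal_coil(self, clean_solenoid):
        curve, truth = clean_solenoid
        core = smooth_core(curve, 12.0)
        frames = parallel_transport_frames(tangent_field(core), seed=2)
        profile = winding_number(project_normal_bundle(curve, core, frames))
        steps = np.diff(profile.w[truth.lrr_start + 8 : truth.lrr_end - 8])
        assert steps.min() > -0.02

    def test_orientation_normalized_and_handedness_reported(self):
        t = np.arange(200)
        # clockwise circle: raw winding would be negative
        xy = np.column_stack(
            [np.cos(-2 * np.pi * t / 200), np.sin(-2 * np.pi * t / 200)]
        )
        profile = winding_number(PlanarCurve(xy=xy))
        assert profile.w[-1] > 0
        assert profile.handedness == -1

    def test_near_origin_point_rejected(self):
        xy = np.ones((50, 2))
        xy[25] = [1e-9, 1e-9]
        with pytest.raises(NumericalError, match="25"):
            winding_number(PlanarCurve(xy=xy))
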