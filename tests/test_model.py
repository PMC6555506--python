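import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from snakuscules.model import (
    DegenerateSnakeError,
    Snake,
    WeightProfile,
    closed_form_blob_energy,
    discrete_energy,
    energy_gradient,
    normalized_energy,
    symmetrizing_exponent,
)

RHO3 = 2.0 ** (-1.0 / 3.0)


class TestWeightProfile:
    def test_inner_core_is_negative(self, profile3d):
        for R in (10.0, 15.0, 23.0):
            assert profile3d.weight(0.0, R) < 0

    def test_zero_outside_footprint(self, profile3d):
        for R in (10.0, 20.0):
            edge = R + profile3d.delta_R / 2.0
            assert profile3d.weight(edge, R) == 0.0
            assert profile3d.weight(edge + 3.0, R) == 0.0

    def test_annulus_is_positive(self, profile3d):
        R = 20.0
        r_mid = 0.5 * (RHO3 * R + R)  # middle of the annulus
        assert profile3d.weight(r_mid, R) > 0

    @pytest.mark.parametrize("ndim", [2, 3])
    @pytest.mark.parametrize("R", [10.0, 20.0, 33.7])
    def test_zero_radial_moment(self, ndim, R):
        # the d-dimensional radial moment of S must vanish: this is what
        # makes constant images energy-free
        prof = WeightProfile(delta_R=4.0, ndim=ndim)
        hi = R + prof.delta_R
        val, _ = quad(lambda r: prof.weight(r, R) * r ** (ndim - 1), 0, hi, limit=400)
        scale, _ = quad(
            lambda r: abs(prof.weight(r, R)) * r ** (ndim - 1), 0, hi, limit=400
        )
        assert abs(val) <= 1e-9 * scale

    def test_moment_zero_for_R20_dR4(self):
        prof = WeightProfile(delta_R=4.0, ndim=3)
        val, _ = quad(lambda r: prof.weight(r, 20.0) * r * r, 0, 24.0, limit=400)
        assert abs(val) < 1e-9 * 20.0**3

    def test_weight_grad_r_matches_fd(self, profile3d):
        R = 15.0
        rs = np.linspace(0.1, R + 3.0, 157)
        h = 1e-6
        fd = (profile3d.weight(rs + h, R) - profile3d.weight(rs - h, R)) / (2 * h)
        np.testing.assert_allclose(profile3d.weight_grad_r(rs, R), fd, atol=1e-5)

    def test_weight_grad_R_matches_fd(self, profile3d):
        R = 15.0
        rs = np.linspace(0.1, R + 3.0, 157)
        h = 1e-6
        fd = (profile3d.weight(rs, R + h) - profile3d.weight(rs, R - h)) / (2 * h)
        np.testing.assert_allclose(profile3d.weight_grad_R(rs, R), fd, atol=1e-5)

    def test_degenerate_radius_rejected(self, profile3d):
        with pytest.raises(DegenerateSnakeError):
            profile3d.weight(1.0, profile3d.delta_R)

    def test_transition_widths_fixed_while_footprint_scales(self, profile3d):
        # the ramp width does not change with R: the transition region of
        # S(.; R) is congruent for different R, just shifted
        rs = np.linspace(-2.0, 2.0, 41)
        w1 = profile3d.weight(18.0 + rs, 18.0)
        w2 = profile3d.weight(30.0 + rs, 30.0)
        np.testing.assert_allclose(w1, w2, atol=1e-12)


class TestSnake:
    def test_radius_and_center(self):
        s = Snake(px=3.0, qx=13.0, cross=np.array([7.0, 9.0]))
        assert s.radius == 5.0
        np.testing.assert_allclose(s.center, [7.0, 9.0, 8.0])
        np.testing.assert_allclose(s.p, [7.0, 9.0, 3.0])
        np.testing.assert_allclose(s.q, [7.0, 9.0, 13.0])

    def test_from_center_radius_roundtrip(self):
        s = Snake.from_center_radius((4.0, 5.0, 6.0), 2.5)
        np.testing.assert_allclose(s.center, [4.0, 5.0, 6.0])
        assert s.radius == 2.5

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            Snake(px=5.0, qx=5.0, cross=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            Snake.from_center_radius((1.0, 2.0, 3.0), 0.0)


class TestClosedFormEnergy:
    def test_contour_inside_blob_is_zero(self):
        assert closed_form_blob_energy(0.5, 1.0) == 0.0

    def test_middle_branch(self):
        expected = -(8.0 / 3.0) * np.pi * (1.1**3 - 1.0)
        assert closed_form_blob_energy(1.1, 1.0) == pytest.approx(expected)

    def test_saturated_branch_at_optimum(self):
        assert closed_form_blob_energy(2 ** (1 / 3), 1.0) == pytest.approx(
            -(8.0 / 3.0) * np.pi
        )

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            closed_form_blob_energy(-1.0, 1.0)
        with pytest.raises(ValueError):
            closed_form_blob_energy(1.0, 0.0)


class TestNormalizedEnergy:
    def test_value_at_optimum(self):
        e = normalized_energy(-(8.0 / 3.0) * np.pi, 2 ** (1 / 3), 3.0)
        assert e == pytest.approx(-(4.0 / 3.0) * np.pi)

    def test_zero_energy_stays_zero(self):
        assert normalized_energy(0.0, 5.0, 3.0) == 0.0

    def test_unique_minimum_at_rescaled_blob_radius(self):
        # dense 1-D scan: exactly one local minimum, at R = 2**(1/3) r0
        r0 = 1.0
        Rs = np.linspace(0.3, 4.0, 20000)
        E = normalized_energy(closed_form_blob_energy(Rs, r0), Rs, 3.0)
        interior = (E[1:-1] < E[:-2]) & (E[1:-1] <= E[2:])
        minima = np.flatnonzero(interior) + 1
        # collapse plateau-adjacent indices
        groups = np.split(minima, np.flatnonzero(np.diff(minima) > 1) + 1)
        assert len(groups) == 1
        R_min = Rs[groups[0]].mean()
        assert abs(R_min - 2 ** (1 / 3) * r0) <= 0.02 * 2 ** (1 / 3) * r0

    def test_gradient_symmetry_at_optimum(self):
        # |dE/dR| just below and above the optimum agree within 1% when
        # alpha = 3
        r0, alpha = 1.0, 3.0
        eps = 1e-3 * r0
        h = 1e-7
        R_star = 2 ** (1 / 3) * r0

        def nE(R):
            return normalized_energy(closed_form_blob_energy(R, r0), R, alpha)

        left = (nE(R_star - eps + h) - nE(R_star - eps - h)) / (2 * h)
        right = (nE(R_star + eps + h) - nE(R_star + eps - h)) / (2 * h)
        assert abs(abs(left) - abs(right)) <= 0.01 * abs(left)

    def test_symmetrizing_exponent_3d(self):
        assert symmetrizing_exponent(ndim=3) == pytest.approx(3.0, abs=1e-3)

    def test_symmetrizing_exponent_2d(self):
        assert symmetrizing_exponent(ndim=2) == pytest.approx(2.0, abs=1e-3)


class TestDiscreteEnergy:
    def test_all_zero_image(self, profile3d):
        img = np.zeros((48, 48, 48))
        s = Snake.from_center_radius((24.0, 23.5, 25.1), 12.0)
        assert discrete_energy(img, s, profile3d) == 0.0

    def test_constant_image_zero_energy(self, profile3d):
        img = np.full((64, 64, 64), 0.7)
        s = Snake.from_center_radius((31.5, 31.7, 30.9), 12.3)
        assert abs(discrete_energy(img, s, profile3d)) < 1e-6

    @given(
        cz=st.floats(24.0, 40.0),
        cy=st.floats(24.0, 40.0),
        cx=st.floats(24.0, 40.0),
        R=st.floats(8.5, 15.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_constant_image_zero_energy_any_position(self, cz, cy, cx, R):
        prof = WeightProfile(delta_R=4.0, ndim=3)
        img = np.full((64, 64, 64), 0.4)
        s = Snake.from_center_radius((cz, cy, cx), R)
        assert abs(discrete_energy(img, s, prof)) < 1e-6

    def test_matches_closed_form_at_optimum(self, voxelized_blob_96):
        img, center = voxelized_blob_96
        # narrow ramps approximate the sharp-limit weight the closed form
        # assumes
        prof = WeightProfile(delta_R=0.3, ndim=3)
        R = 2 ** (1 / 3) * 10.0
        s = Snake.from_center_radius(center, R)
        expected = closed_form_blob_energy(R, 10.0) / (2 * R) ** 3
        assert discrete_energy(img, s, prof) == pytest.approx(expected, rel=0.02)

    def test_degenerate_snake_rejected(self, profile3d):
        img = np.zeros((32, 32, 32))
        s = Snake.from_center_radius((16.0, 16.0, 16.0), 3.0)
        with pytest.raises(DegenerateSnakeError):
            discrete_energy(img, s, profile3d)

    def test_constant_image_2d(self, profile2d):
        img = np.full((96, 96), 0.3)
        s = Snake.from_center_radius((47.2, 48.6), 14.1)
        assert abs(discrete_energy(img, s, profile2d)) < 1e-6


def fd_gradient(img, s, prof, h=1e-3):
    """Central finite differences; cross-axis entries are per-point partials
    (half the derivative of a shared p/q shift)."""
    out = [
        (
            discrete_energy(img, Snake(s.px + h, s.qx, s.cross), prof)
            - discrete_energy(img, Snake(s.px - h, s.qx, s.cross), prof)
        )
        / (2 * h),
        (
            discrete_energy(img, Snake(s.px, s.qx + h, s.cross), prof)
            - discrete_energy(img, Snake(s.px, s.qx - h, s.cross), prof)
        )
        / (2 * h),
    ]
    for a in range(s.cross.size):
        d = np.zeros(s.cross.size)
        d[a] = h
        out.append(
            0.5
            * (
                discrete_energy(img, Snake(s.px, s.qx, s.cross + d), prof)
                - discrete_energy(img, Snake(s.px, s.qx, s.cross - d), prof)
            )
            / (2 * h)
        )
    return np.array(out)


class TestEnergyGradient:
    def test_uniform_image_zero_gradient(self, profile3d):
        img = np.full((64, 64, 64), 0.5)
        s = Snake.from_center_radius((31.8, 32.4, 30.6), 11.0)
        assert np.max(np.abs(energy_gradient(img, s, profile3d))) < 1e-6

    def test_matches_finite_differences(self, smooth_field, profile3d):
        rng = np.random.default_rng(42)
        for _ in range(25):
            c = rng.uniform(15, 33, 3)
            R = rng.uniform(9, 14)
            s = Snake.from_center_radius(c, R)
            g = energy_gradient(smooth_field, s, profile3d)
            fd = fd_gradient(smooth_field, s, profile3d)
            np.testing.assert_allclose(g, fd, rtol=1e-3, atol=1e-9)

    def test_matches_finite_differences_2d(self, profile2d):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(3)
        img = ndi.gaussian_filter(rng.random((96, 96)), 2.0)
        for _ in range(10):
            s = Snake.from_center_radius(rng.uniform(30, 60, 2), rng.uniform(9, 15))
            g = energy_gradient(img, s, profile2d)
            fd = fd_gradient(img, s, profile2d)
            np.testing.assert_allclose(g, fd, rtol=1e-3, atol=1e-9)

    def test_symmetric_image_has_zero_cross_gradient(self, profile3d):
        # image symmetric about the snake's y-plane -> y-component cancels
        grids = np.ogrid[0:64, 0:64, 0:64]
        cy = 31.5
        img = np.exp(-((grids[1] - cy) ** 2) / 50.0) * np.ones((64, 64, 64))
        s = Snake.from_center_radius((30.9, cy, 32.2), 10.0)
        g = energy_gradient(img, s, profile3d)
        # gradient order is (px, qx, z, y): the y entry is index 3
        assert abs(g[3]) < 1e-10
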