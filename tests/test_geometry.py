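"""Shape models: quartic coefficients, morphing, spiculation, voxelization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbcsim.geometry import (
    BiconcaveParams,
    GeometryError,
    ImplicitCoeffs,
    RotatedShape,
    SpiculeSpec,
    Sphere,
    default_spacing,
    discretize,
    equivalent_diameter,
    implicit_f,
    is_inside,
    make_spiculated,
    morph_shape,
    quartic_volume,
    shape_from_config,
    solve_biconcave_coeffs,
)

D7 = BiconcaveParams(d=7.0, b=1.26, c=4.34, h=2.45)  # standard ratios of d = 7


class TestBiconcaveCoeffs:
    def test_sphere_limit_coefficients_factor_as_perfect_square(self):
        # S=1, P=Q=-2 rho^2, R=rho^4 must reproduce (r^2 + z^2 - rho^2)^2,
        # confirming the quartic evaluator is posed as written
        rho = 1.7
        coeffs = ImplicitCoeffs(S=1.0, P=-2 * rho**2, Q=-2 * rho**2, R=rho**4)
        r = np.linspace(0, 3, 40)[:, None]
        z = np.linspace(-3, 3, 41)[None, :]
        np.testing.assert_allclose(
            implicit_f(r, z, coeffs), (r**2 + z**2 - rho**2) ** 2, atol=1e-10
        )

    def test_standard_cell_satisfies_all_constraints(self):
        coeffs = solve_biconcave_coeffs(D7)
        assert abs(implicit_f(3.5, 0.0, coeffs)) < 1e-8
        assert abs(implicit_f(0.0, 0.63, coeffs)) < 1e-8
        assert abs(implicit_f(2.17, 1.225, coeffs)) < 1e-8
        # thickness extremum: df/dr = 0 at (c/2, h/2)
        rc, zh, eps = 2.17, 1.225, 1e-6
        dfdr = (implicit_f(rc + eps, zh, coeffs) - implicit_f(rc - eps, zh, coeffs)) / (2 * eps)
        assert abs(dfdr) < 1e-5

    def test_flat_cell_without_concavity_is_rejected(self):
        with pytest.raises(GeometryError, match="degenerate"):
            BiconcaveParams(d=7.0, b=2.45, c=4.34, h=2.45)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        d=st.floats(2.0, 9.0),
        rb=st.floats(0.10, 0.30),
        rc=st.floats(0.50, 0.75),
        rh=st.floats(0.25, 0.45),
    )
    def test_constraint_residuals_small_over_physiologic_ratio_ranges(self, d, rb, rc, rh):
        if rh <= rb + 1e-3:
            rb, rh = rh / 2, rh  # keep b < h
        p = BiconcaveParams(d=d, b=rb * d, c=rc * d, h=rh * d)
        coeffs = solve_biconcave_coeffs(p)  # residual check built in (tol 1e-8)
        assert np.isfinite(coeffs.as_array()).all()


class TestInsidePredicate:
    def test_point_at_full_diameter_is_outside(self):
        coeffs = solve_biconcave_coeffs(D7)
        assert not is_inside([7.0, 0.0, 0.0], coeffs)

    def test_point_on_thickness_ring_is_inside(self):
        coeffs = solve_biconcave_coeffs(D7)
        assert is_inside([2.17, 0.0, 0.0], coeffs)

    def test_origin_inside_iff_constant_term_nonpositive(self):
        coeffs = solve_biconcave_coeffs(D7)
        assert bool(is_inside([0.0, 0.0, 0.0], coeffs)) == (coeffs.R <= 0)


class TestMorph:
    def test_t0_matches_plain_biconcave_coefficients(self):
        shape = morph_shape(D7, 0.0)
        np.testing.assert_allclose(
            shape.coeffs.as_array(), solve_biconcave_coeffs(D7).as_array(), rtol=1e-12
        )

    def test_t1_voxelization_equals_equal_volume_sphere(self):
        shape = morph_shape(D7, 1.0)
        assert isinstance(shape, Sphere)
        v0 = quartic_volume(solve_biconcave_coeffs(D7))
        np.testing.assert_allclose(4 / 3 * np.pi * shape.radius**3, v0, rtol=1e-6)
        ref = Sphere(radius=shape.radius)
        ds = 0.05
        ga, gb = discretize(shape, ds), discretize(ref, ds)
        assert ga.n_dipoles == gb.n_dipoles

    @pytest.mark.parametrize("t", [0.25, 0.5, 0.75])
    def test_equivalent_diameter_conserved_along_morph(self, t):
        ds = 0.04
        d0 = equivalent_diameter(discretize(morph_shape(D7, 0.0), ds))
        dt = equivalent_diameter(discretize(morph_shape(D7, t), ds))
        # one voxel-volume equivalent tolerance
        assert abs(dt - d0) < 2 * ds

    def test_central_thickness_monotone_in_morph_fraction(self):
        ds = 0.02
        thickness = []
        for t in [0.0, 0.25, 0.5, 0.75, 1.0]:
            grid = discretize(morph_shape(D7, t), ds)
            on_axis = grid.positions[np.hypot(grid.positions[:, 0], grid.positions[:, 1]) < ds]
            thickness.append(on_axis[:, 2].max() - on_axis[:, 2].min())
        assert all(b >= a - ds for a, b in zip(thickness, thickness[1:]))
        assert thickness[-1] > thickness[0]

    def test_morph_fraction_out_of_range_rejected(self):
        with pytest.raises(GeometryError):
            morph_shape(D7, 1.5)


class TestSpiculation:
    def test_zero_amplitude_equals_plain_sphere(self):
        spec = SpiculeSpec(base_diameter=2.0, amplitude=0.0, n_spicules=10, seed=4)
        grid_spiky = discretize(make_spiculated(spec), 0.05)
        grid_plain = discretize(Sphere(radius=1.0), 0.05)
        assert grid_spiky.n_dipoles == grid_plain.n_dipoles

    def test_seeded_shape_is_bit_reproducible(self):
        spec = SpiculeSpec(base_diameter=2.0, amplitude=0.2, n_spicules=20, seed=11)
        g1 = discretize(make_spiculated(spec), 0.05)
        g2 = discretize(make_spiculated(spec), 0.05)
        np.testing.assert_array_equal(g1.positions, g2.positions)

    def test_protrusions_add_volume(self):
        spec = SpiculeSpec(base_diameter=2.0, amplitude=0.2, n_spicules=20, seed=11)
        spiky = discretize(make_spiculated(spec), 0.05)
        plain = discretize(Sphere(radius=1.0), 0.05)
        assert spiky.n_dipoles > plain.n_dipoles

    def test_invalid_spec_rejected(self):
        with pytest.raises(GeometryError):
            SpiculeSpec(base_diameter=2.0, amplitude=-0.1)
        with pytest.raises(GeometryError):
            SpiculeSpec(base_diameter=2.0, amplitude=0.1, n_spicules=0)


class TestDiscretize:
    def test_sphere_voxel_count_matches_analytic_volume(self):
        grid = discretize(Sphere(radius=0.25), 0.05)
        expected = np.pi / 6 * (0.5 / 0.05) ** 3  # about 524
        assert abs(grid.n_dipoles - expected) / expected < 0.05

    def test_lattice_shift_by_one_pitch_preserves_count(self):
        ds = 0.05
        g0 = discretize(Sphere(radius=0.25), ds)
        g1 = discretize(Sphere(radius=0.25), ds, origin_shift=(ds, 0.0, 0.0))
        assert g0.n_dipoles == g1.n_dipoles

    def test_biconcave_occupies_less_than_enclosing_sphere(self):
        ds = 0.1
        disc = discretize(morph_shape(D7, 0.0), ds)
        ball = discretize(Sphere(radius=3.5), ds)
        assert disc.n_dipoles < ball.n_dipoles

    def test_empty_grid_raises(self):
        # shift the lattice so no cell centre falls inside the tiny sphere
        with pytest.raises(GeometryError, match="empty"):
            discretize(Sphere(radius=0.01), 0.5, origin_shift=(0.25, 0.25, 0.25))

    def test_voxel_count_scales_inverse_cube_of_spacing(self):
        base = 0.08
        counts = {
            f: discretize(Sphere(radius=0.5), base / f).n_dipoles for f in (1.0, 2.0, 4.0)
        }
        for f in (2.0, 4.0):
            assert abs(counts[f] / counts[1.0] - f**3) / f**3 < 0.05

    def test_fractional_occupancy_reproduces_volume_closely(self):
        grid = discretize(Sphere(radius=0.25), 0.05, supersample=4)
        v_true = 4 / 3 * np.pi * 0.25**3
        assert abs(grid.volume - v_true) / v_true < 0.01


class TestSpacingAndDiameter:
    def test_default_spacing_satisfies_mkd_rule(self):
        k = 2 * np.pi * 1.33 / 0.472
        m = 1.053 + 1e-4j
        assert abs(m * k * default_spacing(m, k)) == pytest.approx(0.45, abs=1e-12)

    def test_index_matched_and_scaling_limits(self):
        assert default_spacing(1.0, 2.0) == pytest.approx(0.225)
        assert default_spacing(1.0, 4.0) == pytest.approx(0.1125)

    def test_equivalent_diameter_of_voxelized_sphere(self):
        grid = discretize(Sphere(radius=0.5), 0.05)
        assert abs(equivalent_diameter(grid) - 1.0) < 0.02

    def test_single_dipole_formula(self):
        from rbcsim.geometry import DipoleGrid

        grid = DipoleGrid(
            positions=np.zeros((1, 3)),
            spacing=0.1,
            indices=np.zeros((1, 3), dtype=int),
            grid_shape=(1, 1, 1),
        )
        assert equivalent_diameter(grid) == pytest.approx((6 * 0.1**3 / np.pi) ** (1 / 3))

    def test_equivalent_diameter_invariant_under_rigid_rotation(self):
        spec = SpiculeSpec(base_diameter=1.0, amplitude=0.1, n_spicules=12, seed=2)
        shape = make_spiculated(spec)
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        d0 = equivalent_diameter(discretize(shape, 0.03))
        d1 = equivalent_diameter(discretize(RotatedShape(shape, rot), 0.03))
        assert abs(d1 - d0) / d0 < 0.02


class TestShapeConfig:
    @pytest.mark.parametrize(
        "cfg",
        [
            {"type": "sphere", "d": 1.0},
            {"type": "biconcave", "d": 5.0},
            {"type": "morph", "d": 5.0, "t": 0.5},
            {"type": "spiculated", "d": 1.0, "spicule": {"amplitude": 0.08, "seed": 3}},
        ],
    )
    def test_round_trips_to_a_discretizable_shape(self, cfg):
        grid = discretize(shape_from_config(cfg), 0.05)
        assert grid.n_dipoles > 0

    def test_unknown_type_rejected(self):
        with pytest.raises(GeometryError):
            shape_from_config({"type": "torus"})
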