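"""Coupled-dipole solver: polarizability, dense oracles, far field, Mie checks."""

import numpy as np
import pytest

from rbcsim.dda import (
    DDAProblem,
    IncidentWave,
    OpticalParams,
    amplitude_matrix,
    mueller_from_amplitudes,
    polarizability,
    simulate_mm,
    simulate_mm_curve,
    solve_fields,
)
from rbcsim.geometry import DipoleGrid, Sphere, SpiculeSpec, discretize, make_spiculated
from rbcsim.mie import MieInput, mie_amplitudes, mie_mueller
from rbcsim.orientation import EulerOrientation

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])


def _wave(direction=Z, pol=X):
    return IncidentWave(direction=direction, polarization=pol.astype(complex))


def _tiny_grid(indices, spacing=0.02):
    idx = np.asarray(indices, dtype=int)
    n = int(idx.max()) + 1
    pos = (idx - (n - 1) / 2.0) * spacing
    return DipoleGrid(
        positions=pos, spacing=spacing, indices=idx, grid_shape=(n, n, n)
    )


class TestPolarizability:
    def test_index_matched_medium_gives_zero(self):
        assert polarizability(1.0, 0.02, 17.7) == 0

    def test_clausius_mossotti_leading_order(self):
        m, d = 1.01, 0.02
        a = polarizability(m, d, 17.7, kind="cm")
        expected = 3 * d**3 / (4 * np.pi) * (m**2 - 1) / (m**2 + 2)
        assert a == pytest.approx(expected, rel=1e-12)

    def test_ldr_differs_from_cm_at_second_order_in_kd(self):
        m, d = 1.053, 0.02
        rel = {
            k: abs(polarizability(m, d, k, "ldr") / polarizability(m, d, k, "cm") - 1)
            for k in (5.0, 10.0)
        }
        assert 0 < rel[5.0] < 0.05
        # leading correction scales as (kd)^2: doubling k quadruples it
        assert rel[10.0] / rel[5.0] == pytest.approx(4.0, rel=0.1)


class TestSolver:
    def test_single_dipole_solution_is_alpha_times_incident(self, optics):
        grid = _tiny_grid([[0, 0, 0]])
        sol = solve_fields(grid, _wave(), optics)
        alpha = polarizability(optics.m_rel, grid.spacing, optics.k_medium, "ldr", _wave())
        np.testing.assert_allclose(sol.polarizations, [[alpha, 0, 0]], rtol=1e-12)

    def test_two_dipoles_match_dense_6x6_solve(self, optics):
        grid = _tiny_grid([[0, 0, 0], [1, 0, 0]])
        prob = DDAProblem(grid, optics, tol=1e-12)
        wave = _wave()
        sol = prob.solve(wave)
        alpha = polarizability(optics.m_rel, grid.spacing, optics.k_medium, "ldr", wave)
        dense = prob.dense_matrix(alpha)
        ref = np.linalg.solve(dense, prob.incident_field(wave).ravel())
        np.testing.assert_allclose(sol.polarizations.ravel(), ref, atol=1e-12 * np.abs(ref).max())

    def test_fft_matvec_equals_dense_matvec_on_5cubed(self, optics):
        idx = np.array([(i, j, k) for i in range(5) for j in range(5) for k in range(5)])
        grid = _tiny_grid(idx)
        prob = DDAProblem(grid, optics)
        alpha = polarizability(optics.m_rel, grid.spacing, optics.k_medium)
        rng = np.random.default_rng(0)
        p = rng.normal(size=3 * grid.n_dipoles) + 1j * rng.normal(size=3 * grid.n_dipoles)
        av = prob._alpha_vector(alpha)
        y_fft = prob.matvec(p, av)
        y_dense = prob.dense_matrix(alpha) @ p
        np.testing.assert_allclose(y_fft, y_dense, atol=1e-12 * np.abs(y_dense).max())

    def test_fft_solve_equals_dense_solve_on_6cubed(self, optics):
        idx = np.array([(i, j, k) for i in range(6) for j in range(6) for k in range(6)])
        grid = _tiny_grid(idx)
        prob = DDAProblem(grid, optics, tol=1e-12)
        wave = _wave()
        sol = prob.solve(wave)
        alpha = polarizability(optics.m_rel, grid.spacing, optics.k_medium, "ldr", wave)
        ref = np.linalg.solve(prob.dense_matrix(alpha), prob.incident_field(wave).ravel())
        err = np.abs(sol.polarizations.ravel() - ref).max() / np.abs(ref).max()
        assert err < 1e-10

    def test_oversized_lattice_pitch_rejected(self, optics):
        grid = _tiny_grid([[0, 0, 0], [1, 0, 0]], spacing=0.04)
        with pytest.raises(ValueError, match="refine the lattice"):
            DDAProblem(grid, optics)


class TestFarField:
    def test_single_dipole_forward_amplitudes_equal(self, optics):
        grid = _tiny_grid([[0, 0, 0]])
        prob = DDAProblem(grid, optics)
        su = prob.solve(_wave(pol=X))
        sv = prob.solve(_wave(pol=Y))
        s = amplitude_matrix(prob, (su, sv), Z)
        assert s[0, 0] == pytest.approx(s[1, 1], rel=1e-12)
        assert abs(s[0, 1]) < 1e-14 * abs(s[0, 0])

    def test_rigid_translation_changes_only_global_phase(self, optics):
        grid = _tiny_grid([[0, 0, 0], [1, 1, 0], [0, 1, 1]])
        shifted = DipoleGrid(
            positions=grid.positions + np.array([0.3, -0.2, 0.15]),
            spacing=grid.spacing,
            indices=grid.indices,
            grid_shape=grid.grid_shape,
        )
        n_hat = np.array([np.sin(1.0), 0, np.cos(1.0)])
        mats = []
        for g in (grid, shifted):
            prob = DDAProblem(g, optics)
            su, sv = prob.solve(_wave(pol=X)), prob.solve(_wave(pol=Y))
            mats.append(amplitude_matrix(prob, (su, sv), n_hat))
        np.testing.assert_allclose(np.abs(mats[0]), np.abs(mats[1]), rtol=1e-9, atol=1e-20)

    def test_small_sphere_amplitudes_match_mie(self, optics, small_sphere_grid):
        prob = DDAProblem(small_sphere_grid, optics)
        su, sv = prob.solve(_wave(pol=X)), prob.solve(_wave(pol=Y))
        deq = (6 * small_sphere_grid.volume / np.pi) ** (1 / 3)
        inp = MieInput(x=optics.k_medium * deq / 2, m=optics.m_rel)
        for th in (0.0, 40.0, 60.0, 120.0):
            n_hat = np.array([np.sin(np.deg2rad(th)), 0, np.cos(np.deg2rad(th))])
            s = amplitude_matrix(prob, (su, sv), n_hat)
            s1, s2 = mie_amplitudes(inp, th)
            # complex agreement (magnitude and phase) within discretization error
            assert s[1, 1] == pytest.approx(s1, rel=0.08)
            assert s[0, 0] == pytest.approx(s2, rel=0.08)
            assert abs(s[0, 1]) < 1e-3 * abs(s1)


class TestMuellerFromAmplitudes:
    def test_identity_amplitude_gives_identity_mueller(self):
        np.testing.assert_allclose(mueller_from_amplitudes(np.eye(2)), np.eye(4), atol=1e-14)

    def test_diagonal_amplitudes_zero_sphere_forbidden_elements(self):
        mm = mueller_from_amplitudes(np.diag([1.3 + 0.2j, 0.7 - 0.1j]))
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3), (2, 0), (3, 0), (2, 1), (3, 1)]:
            assert abs(mm[i, j]) < 1e-14

    def test_random_amplitude_matrix_maps_stokes_consistently(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=(2, 2)) + 1j * rng.normal(size=(2, 2))
        mm = mueller_from_amplitudes(s)
        # independent route: propagate the horizontal-polarization field
        e_in = np.array([1.0, 0.0])  # (parallel, perpendicular)
        e_out = s @ e_in
        stokes_out = np.array(
            [
                abs(e_out[0]) ** 2 + abs(e_out[1]) ** 2,
                abs(e_out[0]) ** 2 - abs(e_out[1]) ** 2,
                2 * (e_out[0] * e_out[1].conj()).real,
                -2 * (e_out[0] * e_out[1].conj()).imag,
            ]
        )
        np.testing.assert_allclose(mm @ [1, 1, 0, 0], stokes_out, atol=1e-12)


class TestSimulate:
    def test_sphere_mm_is_orientation_invariant(self, optics):
        # a sphere expressed as an orientation-dependent shape type
        shape = make_spiculated(SpiculeSpec(base_diameter=0.3, amplitude=0.0, seed=1))
        oris = [
            [EulerOrientation(alpha=0.0, beta=0.0)],
            [EulerOrientation(alpha=123.0, beta=77.0, gamma=31.0)],
        ]
        pairs = [simulate_mm(shape, optics, orientations=o)[0] for o in oris]
        # invariance holds up to the cubic lattice's own anisotropy (~1e-3)
        np.testing.assert_allclose(pairs[0].mm60, pairs[1].mm60, atol=5e-3)
        np.testing.assert_allclose(pairs[0].mm120, pairs[1].mm120, atol=8e-3)
        # the Sphere shape type collapses orientations, making this exact
        exact = [
            simulate_mm(Sphere(radius=0.15), optics, orientations=o)[0] for o in oris
        ]
        np.testing.assert_allclose(exact[0].mm60, exact[1].mm60, atol=1e-12)

    def test_small_sphere_normalized_elements_match_mie(self, optics):
        curve, meta = simulate_mm_curve(
            Sphere(radius=0.15), optics, angles=np.arange(0, 181, 5.0)
        )
        deq = (6 * meta["volume"] / np.pi) ** (1 / 3)
        mie_raw = mie_mueller(
            MieInput(x=optics.k_medium * deq / 2, m=optics.m_rel), curve.angles
        ).mm
        # forward-normalized comparison over all angles
        dev_fwd = np.abs(curve.mm / curve.mm[0, 0, 0] - mie_raw / mie_raw[0, 0, 0]).max()
        assert dev_fwd < 0.01

    def test_physicality_of_averaged_output(self, optics):
        shape = make_spiculated(SpiculeSpec(base_diameter=0.3, amplitude=0.03, seed=5))
        oris = [EulerOrientation(alpha=a, beta=b) for a, b in [(0, 30), (120, 75), (260, 140)]]
        pair, _ = simulate_mm(shape, optics, orientations=oris)
        for mm in (pair.mm60, pair.mm120):
            assert np.abs(mm).max() <= 1 + 1e-9

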