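"""Centroid computation, orbital assignment, and the adaptive fixed point."""

import numpy as np
import pytest

from adaptneo.adaptive import (
    AdaptiveSettings,
    adaptive_step,
    assign_orbitals,
    compute_centroids,
    run_adaptive_neo,
)
from adaptneo.basis import BasisSet, GaussianShell, load_basis
from adaptneo.molsys import AtomicCenter, MolecularSystem, transform
from adaptneo.scf import SCFState, compute_integrals, run_neo_scf
from adaptneo.units import ANGSTROM_PER_BOHR, PROTON_MASS


class TestSettings:
    def test_damping_bounds(self):
        with pytest.raises(ValueError):
            AdaptiveSettings(damping_factor=0.0)
        with pytest.raises(ValueError):
            AdaptiveSettings(damping_factor=1.2)
        assert AdaptiveSettings(damping_factor=0.5).damping_factor == 0.5

    def test_threshold_positive(self):
        with pytest.raises(ValueError):
            AdaptiveSettings(position_threshold=-1e-5)


class TestCentroids:
    def test_single_s_orbital_centroid_at_center(self):
        """A symmetric s-type nuclear orbital has its centroid exactly at
        the basis center."""
        pos = np.array([0.3, -0.5, 1.2])
        sys_ = MolecularSystem(
            (AtomicCenter("H", pos, 1, is_quantum=True),), +1
        )
        bp = load_basis("et-4s", "proton", sys_)
        be = BasisSet("electron", ())
        ints = compute_integrals(sys_, be, bp)
        from adaptneo.scf import build_nuclear_fock, solve_roothaan

        F = build_nuclear_fock(np.zeros((4, 4)), None, ints, 1)
        C, eps, D = solve_roothaan(F, ints.proton.overlap, 1)
        state = SCFState(mo_coeffs_p=C)
        cen = compute_centroids(state, ints.proton, [0])
        np.testing.assert_allclose(cen[0], pos, atol=1e-10)

    def test_two_center_combination_from_2x2_algebra(self):
        """Equal-weight combination of two s functions: centroid from the
        hand-computable 2x2 position-matrix contraction."""
        a = 0.8
        A, B = np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 2.0])
        sys_ = MolecularSystem(
            (
                AtomicCenter("H", A, 1, is_quantum=True),
                AtomicCenter("H", B, 1, is_quantum=True),
            ),
            +2,
        )
        bp = BasisSet(
            "proton",
            (
                GaussianShell(0, 0, (a,), (1.0,)),
                GaussianShell(1, 0, (a,), (1.0,)),
            ),
            PROTON_MASS,
        )
        ints = compute_integrals(sys_, BasisSet("electron", ()), bp)
        S = ints.proton.overlap
        s01 = S[0, 1]
        # normalized symmetric combination c = (1,1)/sqrt(2 + 2 s01)
        c = np.full(2, 1.0 / np.sqrt(2.0 + 2.0 * s01))
        state = SCFState(mo_coeffs_p=np.column_stack([c, c]))
        cen = compute_centroids(state, ints.proton, [0])[0]
        Z = ints.proton.position_z
        expected_z = (
            c[0] ** 2 * Z[0, 0] + 2 * c[0] * c[1] * Z[0, 1] + c[1] ** 2 * Z[1, 1]
        )
        assert cen[2] == pytest.approx(expected_z, abs=1e-12)
        assert 0.0 < cen[2] < 2.0  # strictly between the centers on the axis
        np.testing.assert_allclose(cen[:2], 0.0, atol=1e-12)

    def test_symmetric_fixture_centroid_at_midpoint(self, hehhe):
        fx, be, bp = hehhe
        state, _, ints = run_neo_scf(fx.system, be, bp)
        assignment = assign_orbitals(state, bp, fx.system, ints.proton.overlap)
        cen = compute_centroids(state, ints.proton, assignment)
        np.testing.assert_allclose(cen[0], [0.0, 0.0, 0.0], atol=1e-10)


class TestAssignment:
    def test_single_orbital_maps_to_single_center(self, hehhe):
        fx, be, bp = hehhe
        state, _, ints = run_neo_scf(fx.system, be, bp)
        assert assign_orbitals(state, bp, fx.system, ints.proton.overlap) == [0]

    def _two_proton_state(self):
        sys_ = MolecularSystem(
            (
                AtomicCenter("H", (0, 0, 0.0), 1, is_quantum=True),
                AtomicCenter("H", (0, 0, 6.0), 1, is_quantum=True),
            ),
            +2,
        )
        bp = BasisSet(
            "proton",
            (
                GaussianShell(0, 0, (8.0,), (1.0,)),
                GaussianShell(1, 0, (8.0,), (1.0,)),
            ),
            PROTON_MASS,
        )
        ints = compute_integrals(sys_, BasisSet("electron", ()), bp)
        return sys_, bp, ints

    def test_well_separated_protons_diagonal_assignment(self):
        sys_, bp, ints = self._two_proton_state()
        C = np.eye(2)  # localized orbitals, one per center
        state = SCFState(mo_coeffs_p=C)
        assert assign_orbitals(state, bp, sys_, ints.proton.overlap) == [0, 1]

    def test_swapped_orbital_order_same_mapping(self):
        sys_, bp, ints = self._two_proton_state()
        C = np.eye(2)[:, ::-1]  # orbital 0 lives on center 1
        state = SCFState(mo_coeffs_p=C)
        assert assign_orbitals(state, bp, sys_, ints.proton.overlap) == [1, 0]


class TestAdaptiveStep:
    def test_fixed_point_no_motion(self, hehhe):
        fx, be, bp = hehhe
        state, _, ints = run_neo_scf(fx.system, be, bp)
        sys2, ints2, disp, cen = adaptive_step(
            state, fx.system, be, bp, AdaptiveSettings(), ints
        )
        assert disp < 1e-10
        assert sys2 is fx.system  # untouched

    def test_damping_halves_displacement(self, hehhe):
        fx, be, bp = hehhe
        start = fx.system.move_center(1, (0.0, 0.0, 0.12))
        state, _, ints = run_neo_scf(start, be, bp)
        full_sys, _, disp_full, cen = adaptive_step(
            state, start, be, bp, AdaptiveSettings(damping_factor=1.0), ints
        )
        half_sys, _, disp_half, _ = adaptive_step(
            state, start, be, bp, AdaptiveSettings(damping_factor=0.5), ints
        )
        assert disp_half == pytest.approx(disp_full / 2.0, rel=1e-10)

    def test_rebuild_reflects_new_positions(self, hehhe):
        fx, be, bp = hehhe
        start = fx.system.move_center(1, (0.0, 0.0, 0.1))
        state, _, ints = run_neo_scf(start, be, bp)
        sys2, ints2, disp, _ = adaptive_step(
            state, start, be, bp, AdaptiveSettings(), ints
        )
        assert disp > 0
        assert not np.allclose(
            ints2.proton.position_z, ints.proton.position_z
        )
        # classical centers never move
        np.testing.assert_array_equal(
            sys2.centers[0].position, start.centers[0].position
        )
        np.testing.assert_array_equal(
            sys2.centers[2].position, start.centers[2].position
        )

    def test_runaway_guard(self, hehhe):
        fx, be, bp = hehhe
        start = fx.system.move_center(1, (0.0, 0.0, 0.1))
        state, _, ints = run_neo_scf(start, be, bp)
        with pytest.raises(RuntimeError, match="runaway"):
            adaptive_step(
                state, start, be, bp,
                AdaptiveSettings(max_step=1e-9), ints,
            )


class TestRunAdaptive:
    def test_symmetric_start_stays_put(self, hehhe_adaptive):
        state, final_system, trace = hehhe_adaptive
        assert state.converged
        assert trace.final_displacement < 1e-5
        np.testing.assert_allclose(
            final_system.centers[1].position, 0.0, atol=1e-5
        )

    def test_off_center_start_returns_to_midpoint(self, hehhe):
        fx, be, bp = hehhe
        start = fx.system.move_center(1, (0.0, 0.0, 0.1))
        state, final_system, trace = run_adaptive_neo(start, be, bp)
        assert (
            abs(final_system.centers[1].position[2]) * ANGSTROM_PER_BOHR
            < 1e-4
        )
        assert trace.final_displacement < 1e-5

    def test_same_basin_starts_agree(self, hbond):
        fx, be, bp = hbond
        runs = []
        for z in (1.80, 1.90):
            st, sysf, _ = run_adaptive_neo(
                fx.system.move_center(1, (0.0, 0.0, z)), be, bp
            )
            runs.append((st.e_total, sysf.centers[1].position[2]))
        (e1, z1), (e2, z2) = runs
        assert abs(z1 - z2) * ANGSTROM_PER_BOHR < 1e-4
        assert abs(e1 - e2) < 1e-6

    def test_trace_recorded_and_bounded(self, hbond_adaptive):
        state, _, trace = hbond_adaptive
        assert len(trace.macrocycle) == state.n_macrocycles
        assert trace.final_displacement < 1e-5
        df = trace.to_frame()
        assert {"macrocycle", "x", "step_norm", "E_total"} <= set(df.columns)

    def test_equivariance_under_rigid_motion(self, hehhe):
        """Translating + rotating the system maps the converged centroid
        the same way."""
        fx, be, bp = hehhe
        start = fx.system.move_center(1, (0.0, 0.0, 0.08))
        st1, sys1, _ = run_adaptive_neo(start, be, bp)
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t = np.array([0.5, -0.25, 0.75])
        moved = transform(start, R, t)
        st2, sys2, _ = run_adaptive_neo(moved, be, bp)
        expected = R @ sys1.centers[1].position + t
        np.testing.assert_allclose(
            sys2.centers[1].position, expected, atol=1e-6
        )
        assert st2.e_total == pytest.approx(st1.e_total, abs=1e-8)

    def test_adaptive_energy_not_above_displaced_fixed_center_runs(
        self, hbond, hbond_adaptive
    ):
        """The adaptive fixed point is at least as low as unoptimized NEO
        runs started from displaced centers in the same basin."""
        fx, be, bp = hbond
        state_ad, _, _ = hbond_adaptive
        for z in (1.78, 1.92):
            st, _, _ = run_neo_scf(
                fx.system.move_center(1, (0.0, 0.0, z)), be, bp
            )
            assert state_ad.e_total <= st.e_total + 1e-8

    def test_no_quantum_centers_rejected(self, water_system):
        be = load_basis("sto-3g", "electron", water_system)
        with pytest.raises(ValueError, match="quantum"):
            run_adaptive_neo(water_system, be, BasisSet("proton", (), PROTON_MASS))
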