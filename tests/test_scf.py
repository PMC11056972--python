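"""Coupled SCF: Fock builds, Roothaan solver, DIIS, energies, convergence."""

import numpy as np
import pytest
import scipy.linalg
import scipy.optimize

from adaptneo.basis import BasisSet, GaussianShell, load_basis
from adaptneo.molsys import AtomicCenter, MolecularSystem, transform
from adaptneo.scf import (
    DIIS,
    ConvergenceSettings,
    build_electronic_fock,
    build_nuclear_fock,
    compute_integrals,
    run_neo_scf,
    solve_roothaan,
    total_energy,
)
from adaptneo.units import PROTON_MASS


from _oracles import rhf_energy_by_direct_minimization


class TestRoothaanSolver:
    def test_diagonal_problem(self):
        F = np.diag([-1.0, 0.0, 1.0])
        C, eps, D = solve_roothaan(F, np.eye(3), n_occ=1, occupation=1.0)
        assert eps[0] == pytest.approx(-1.0)
        assert np.trace(D) == pytest.approx(1.0)
        np.testing.assert_allclose(D, np.diag([1.0, 0.0, 0.0]), atol=1e-14)

    def test_2x2_closed_form(self):
        # H2+-like 2-function problem with printed matrices
        F = np.array([[-1.0, -0.5], [-0.5, -0.6]])
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        C, eps, D = solve_roothaan(F, S, n_occ=1, occupation=2.0)
        # roots of det(F - e S) = 0
        a = 1.0 - 0.4**2
        b = -(-1.0 - 0.6 + 2 * 0.4 * 0.5)
        c = (-1.0) * (-0.6) - 0.25
        roots = np.roots([a, b, c])
        np.testing.assert_allclose(sorted(eps), sorted(roots), atol=1e-12)
        # generalized orthonormality and electron count
        np.testing.assert_allclose(C.T @ S @ C, np.eye(2), atol=1e-12)
        assert np.einsum("pq,pq->", D, S) == pytest.approx(2.0)

    def test_linearly_dependent_function_projected(self):
        # duplicate basis function: one vector is removed, no crash
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        F = np.array([[-0.5, -0.5], [-0.5, -0.5]])
        C, eps, D = solve_roothaan(F, S, n_occ=1, occupation=1.0)
        assert C.shape[1] == 1
        assert eps[0] == pytest.approx(-0.5)

    def test_fully_singular_raises(self):
        S = np.zeros((2, 2))
        with pytest.raises(np.linalg.LinAlgError):
            solve_roothaan(np.eye(2), S, 1)


class TestDIIS:
    def test_single_entry_passthrough(self):
        d = DIIS(depth=10)
        F = np.array([[1.0, 0.2], [0.2, -1.0]])
        d.push(F, np.ones((2, 2)))
        np.testing.assert_array_equal(d.extrapolate(), F)

    def test_identical_entries_no_blowup(self):
        d = DIIS()
        F = np.eye(2)
        err = 1e-3 * np.ones((2, 2))
        d.push(F, err)
        d.push(F, err)
        out = d.extrapolate()
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out, F, atol=1e-8)

    def test_converged_fixed_point(self):
        d = DIIS()
        F = np.array([[0.5, 0.1], [0.1, 0.3]])
        d.push(F + 1e-3, np.full((2, 2), 1e-2))
        d.push(F, np.full((2, 2), 1e-16))
        np.testing.assert_allclose(d.extrapolate(), F, atol=1e-12)

    def test_depth_eviction(self):
        d = DIIS(depth=3)
        for k in range(6):
            d.push(np.eye(2) * k, np.eye(2) * (k + 1))
        assert len(d.focks) == 3
        assert d.focks[0][0, 0] == 3.0


class TestFockBuilds:
    def test_decoupled_limit_is_rhf_fock(self, water_rhf):
        sys_, basis, state, ints = water_rhf
        F_neo = build_electronic_fock(state.density_e, None, ints, 10)
        J = np.einsum("pqrs,rs->pq", ints.tensors.ee, state.density_e)
        K = np.einsum("prqs,rs->pq", ints.tensors.ee, state.density_e)
        np.testing.assert_allclose(
            F_neo, ints.electron.core + J - 0.5 * K, atol=1e-12
        )

    def test_coupling_lowers_electronic_orbital(self, h_atom_neo):
        """Removing the attractive proton term raises the lowest electronic
        orbital energy."""
        fx, be, bp, state, ints = h_atom_neo
        F_with = build_electronic_fock(state.density_e, state.density_p, ints, 1)
        F_without = build_electronic_fock(state.density_e, None, ints, 1)
        e_with = np.linalg.eigvalsh(
            np.linalg.solve(ints.electron.overlap, F_with)
        )
        # generalized eigenvalues via canonical orthogonalization instead
        _, eps_w, _ = solve_roothaan(F_with, ints.electron.overlap, 1)
        _, eps_wo, _ = solve_roothaan(F_without, ints.electron.overlap, 1)
        assert eps_w[0] < eps_wo[0]

    def test_free_proton_fock_positive_spectrum(self):
        sys_ = MolecularSystem(
            (AtomicCenter("H", (0, 0, 0), 1, is_quantum=True),), +1
        )
        bp = load_basis("et-8s", "proton", sys_)
        be = BasisSet("electron", ())
        ints = compute_integrals(sys_, be, bp)
        F = build_nuclear_fock(np.zeros((8, 8)), None, ints, 1)
        _, eps, _ = solve_roothaan(F, ints.proton.overlap, 1)
        assert eps[0] > 0  # pure kinetic: free quantum proton in a finite basis

    def test_electron_attraction_lowers_proton_orbital(self, h_atom_neo):
        fx, be, bp, state, ints = h_atom_neo
        F_with = build_nuclear_fock(state.density_p, state.density_e, ints, 1)
        F_free = build_nuclear_fock(state.density_p, None, ints, 1)
        _, e_w, _ = solve_roothaan(F_with, ints.proton.overlap, 1)
        _, e_f, _ = solve_roothaan(F_free, ints.proton.overlap, 1)
        assert e_w[0] < e_f[0]

    def test_symmetric_system_fock_commutes_with_permutation(self, hehhe):
        fx, be, bp = hehhe
        state, _, ints = run_neo_scf(fx.system, be, bp)
        # mirror z -> -z swaps the two He s-functions (AOs 0 and 2)
        P = np.zeros((3, 3))
        P[0, 2] = P[2, 0] = P[1, 1] = 1.0
        F = state.fock_e
        np.testing.assert_allclose(P @ F @ P, F, atol=1e-7)


class TestEnergies:
    def test_point_charges_only(self):
        sys_ = MolecularSystem(
            (
                AtomicCenter("H", (0, 0, 0), 1),
                AtomicCenter("H", (0, 0, 2.0), 1),
            ),
            +2,
        )
        be = BasisSet("electron", ())
        ints = compute_integrals(sys_, be, None)
        comps = total_energy(None, None, ints, sys_, 0)
        assert comps["E_total"] == pytest.approx(0.5, abs=1e-14)

    def test_components_sum_to_total(self, hbond_adaptive):
        state, _, _ = hbond_adaptive
        c = state.energy_components
        assert c["E_total"] == pytest.approx(
            c["E_electronic"] + c["E_nuclear_quantum"] + c["E_coupling"]
            + c["E_classical_repulsion"],
            abs=1e-10,
        )

    def test_coupling_equals_brute_force_contraction(self, h_atom_neo):
        fx, be, bp, state, ints = h_atom_neo
        brute = -sum(
            state.density_e[p, q] * state.density_p[P, Q]
            * ints.tensors.ep[p, q, P, Q]
            for p in range(state.density_e.shape[0])
            for q in range(state.density_e.shape[0])
            for P in range(state.density_p.shape[0])
            for Q in range(state.density_p.shape[0])
        )
        assert state.energy_components["E_coupling"] == pytest.approx(
            brute, abs=1e-10
        )


class TestRunNEOSCF:
    def test_decoupled_limit_matches_direct_minimization(self, water_rhf):
        """With zero quantum atoms the stepwise driver must land on the
        plain RHF solution, cross-checked against direct energy-functional
        minimization."""
        sys_, basis, state, ints = water_rhf
        ref = rhf_energy_by_direct_minimization(
            ints, n_occ=5, e_nuc=sys_.classical_repulsion()
        )
        assert state.e_total == pytest.approx(ref, abs=1e-8)

    def test_h2_sto3g_literature_value(self):
        # Szabo-Ostlund: RHF/STO-3G at R = 1.4 Bohr gives -1.1167 hartree
        sys_ = MolecularSystem(
            (
                AtomicCenter("H", (0, 0, 0), 1),
                AtomicCenter("H", (0, 0, 1.4), 1),
            ),
            0,
        )
        basis = load_basis("sto-3g", "electron", sys_)
        state, _, _ = run_neo_scf(sys_, basis)
        assert state.e_total == pytest.approx(-1.1167, abs=5e-5)

    def test_particle_number_traces(self, hbond_adaptive):
        state, sys_f, _ = hbond_adaptive
        # recompute overlaps at the final geometry through the state's log
        from adaptneo.fixtures import make_fixture

        fx = make_fixture("hbond_toy")
        be, bp = fx.bases()
        ints = compute_integrals(sys_f, be, bp)
        assert np.einsum(
            "pq,pq->", state.density_e, ints.electron.overlap
        ) == pytest.approx(sys_f.n_electrons, abs=1e-8)
        assert np.einsum(
            "pq,pq->", state.density_p, ints.proton.overlap
        ) == pytest.approx(sys_f.n_quantum, abs=1e-8)

    def test_variational_bound_h_atom(self, h_atom_neo):
        fx, be, bp, state, ints = h_atom_neo
        mu = PROTON_MASS / (PROTON_MASS + 1.0)
        assert state.e_total > -mu / 2.0

    def test_variational_bound_approached_from_above(self, h_atom_neo):
        """Growing both bases lowers the energy but never crosses -mu/2."""
        fx, be, bp, state, ints = h_atom_neo
        small_be = load_basis("et-6s(0.05,50)", "electron", fx.system)
        small_bp = load_basis("et-4s", "proton", fx.system)
        small, _, _ = run_neo_scf(fx.system, small_be, small_bp)
        mu = PROTON_MASS / (PROTON_MASS + 1.0)
        assert small.e_total > state.e_total > -mu / 2.0

    def test_guess_independence(self, hehhe):
        fx, be, bp = hehhe
        state1, _, ints = run_neo_scf(fx.system, be, bp)
        # superposition-like alternative guess: converged densities, scaled
        rng = np.random.default_rng(7)
        D_e0 = state1.density_e + 1e-3 * np.eye(state1.density_e.shape[0])
        D_p0 = state1.density_p.copy()
        state2, _, _ = run_neo_scf(
            fx.system, be, bp, initial_densities=(D_e0, D_p0)
        )
        assert state2.e_total == pytest.approx(state1.e_total, abs=1e-8)

    def test_rigid_motion_invariance(self, hehhe):
        fx, be, bp = hehhe
        state1, _, _ = run_neo_scf(fx.system, be, bp)
        theta = 0.31
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        # rotate about an axis not aligned with the molecule, plus translate
        R2 = R @ np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        moved = transform(fx.system, R2, np.array([0.3, -0.7, 1.1]))
        state2, _, _ = run_neo_scf(moved, be, bp)
        assert state2.e_total == pytest.approx(state1.e_total, abs=1e-8)

    def test_decoupled_split_energies(self, hehhe):
        """Zeroing the electron-proton tensor splits the problem into an
        independent electronic part and a free-proton part."""
        fx, be, bp = hehhe
        ints = compute_integrals(fx.system, be, bp)
        ints.tensors.ep = np.zeros_like(ints.tensors.ep)
        state, _, _ = run_neo_scf(fx.system, be, bp, integrals=ints)
        # electronic reference: direct minimization with the same integrals
        ints_e = compute_integrals(fx.system, be, None)
        e_rhf = rhf_energy_by_direct_minimization(
            ints_e, n_occ=2, e_nuc=fx.system.classical_repulsion()
        )
        # protonic reference: kinetic + classical-nucleus repulsion only
        ints_p = compute_integrals(fx.system, BasisSet("electron", ()), bp)
        F_p = ints_p.proton.core
        _, eps_p, D_p = solve_roothaan(F_p, ints_p.proton.overlap, 1)
        e_p = float(np.einsum("PQ,PQ->", D_p, ints_p.proton.core))
        expected = e_rhf + e_p
        assert state.e_total == pytest.approx(expected, abs=1e-8)

    def test_nonconvergence_carries_trace(self, hehhe):
        from adaptneo.scf import SCFConvergenceError

        fx, be, bp = hehhe
        with pytest.raises(SCFConvergenceError) as exc:
            run_neo_scf(
                fx.system, be, bp,
                ConvergenceSettings(max_macrocycles=1, max_nuclear_cycles=1,
                                    max_electronic_cycles=1),
            )
        assert len(exc.value.iteration_log) > 0

    def test_monotonic_macro_energy_tail(self, hbond):
        """In a plain (fixed-center) NEO run, macrocycle energies do not
        increase once DIIS has stabilized (tolerance 1e-9, final 5 cycles)."""
        fx, be, bp = hbond
        state, _, _ = run_neo_scf(fx.system, be, bp)
        macro_e = [
            r["E_total"] for r in state.iteration_log if r["level"] == "macro"
        ]
        tail = macro_e[-5:]
        assert all(b - a < 1e-9 for a, b in zip(tail, tail[1:]))
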