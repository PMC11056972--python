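"""Stepwise coupled electron-proton restricted Hartree-Fock.

The multicomponent wave function is a product of an electronic closed-shell
determinant and a protonic determinant; the two Roothaan-Hall problems are
coupled through the electron-proton Coulomb interaction.  The driver is
*stepwise*: each macrocycle first converges the nuclear (protonic)
subproblem at fixed electronic density, then converges the electronic
problem at fixed protonic density, and repeats until the inter-macrocycle
energy change and the per-species energy/density/orbital-gradient criteria
are all satisfied.  Both species use Pulay DIIS extrapolation.

A ``post_nuclear_hook`` slot lets the adaptive procedure relocate quantum
centers (and rebuild the integrals) right after each converged nuclear
subcycle — the point in the cycle where the nuclear orbitals are freshly
self-consistent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet
from .integrals import OneParticleMatrices, TwoParticleTensors, one_particle, two_particle
from .molsys import MolecularSystem

__all__ = [
    "ConvergenceSettings",
    "SCFState",
    "NEOIntegrals",
    "SCFConvergenceError",
    "compute_integrals",
    "build_electronic_fock",
    "build_nuclear_fock",
    "solve_roothaan",
    "total_energy",
    "run_neo_scf",
    "DIIS",
    "write_log_csv",
]

log = logging.getLogger(__name__)


class SCFConvergenceError(RuntimeError):
    """SCF failed to converge; carries the iteration log collected so far."""

    def __init__(self, message, iteration_log=None):
        super().__init__(message)
        self.iteration_log = iteration_log or []


@dataclass(frozen=True)
class ConvergenceSettings:
    """All SCF thresholds (atomic units).

    The 1e-8 criteria act inside the nuclear/electronic subcycles on the
    energy change, the RMS density change and the orbital gradient
    (Frobenius norm of FDS - SDF); the 1e-6 hartree criterion acts on the
    energy change between macrocycles.
    """

    e_conv: float = 1e-8
    d_conv: float = 1e-8
    g_conv: float = 1e-8
    neo_e_conv: float = 1e-6
    diis_depth: int = 10
    diis_start: int = 1  # iterations completed before DIIS kicks in
    max_nuclear_cycles: int = 50
    max_electronic_cycles: int = 100
    max_macrocycles: int = 200
    lindep_threshold: float = 1e-10

    def __post_init__(self):
        for name in ("e_conv", "d_conv", "g_conv", "neo_e_conv", "lindep_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NEOIntegrals:
    """All integrals at one geometry (rebuilt whenever a center moves)."""

    electron: OneParticleMatrices | None
    proton: OneParticleMatrices | None
    tensors: TwoParticleTensors


def compute_integrals(
    system: MolecularSystem,
    basis_e: BasisSet,
    basis_p: BasisSet | None,
    max_memory_mb: float = 2000.0,
) -> NEOIntegrals:
    one_e = one_particle(basis_e, system) if basis_e.n_functions else None
    one_p = (
        one_particle(basis_p, system)
        if basis_p is not None and basis_p.n_functions
        else None
    )
    tensors = two_particle(basis_e, basis_p, system, max_memory_mb)
    return NEOIntegrals(one_e, one_p, tensors)


@dataclass
class SCFState:
    """Converged (or in-progress) two-species SCF state."""

    density_e: np.ndarray | None = None
    density_p: np.ndarray | None = None
    fock_e: np.ndarray | None = None
    fock_p: np.ndarray | None = None
    mo_coeffs_e: np.ndarray | None = None
    mo_coeffs_p: np.ndarray | None = None
    orbital_energies_e: np.ndarray | None = None
    orbital_energies_p: np.ndarray | None = None
    energy_components: dict = field(default_factory=dict)
    converged: bool = False
    n_macrocycles: int = 0
    iteration_log: list = field(default_factory=list)

    @property
    def e_total(self) -> float:
        return self.energy_components.get("E_total", np.nan)


def _coulomb(eri: np.ndarray, D: np.ndarray) -> np.ndarray:
    return np.einsum("pqrs,rs->pq", eri, D, optimize=True)


def _exchange(eri: np.ndarray, D: np.ndarray) -> np.ndarray:
    return np.einsum("prqs,rs->pq", eri, D, optimize=True)


def build_electronic_fock(
    density_e: np.ndarray,
    density_p: np.ndarray | None,
    ints: NEOIntegrals,
    n_electrons: int,
) -> np.ndarray:
    """F_e = h_e + J(D_e) - K(D_e)/2 - J_ep(D_p)  (closed-shell convention).

    With a single electron the same-species terms vanish identically.
    """
    F = ints.electron.core.copy()
    if n_electrons > 1:
        F += _coulomb(ints.tensors.ee, density_e)
        F -= 0.5 * _exchange(ints.tensors.ee, density_e)
    if density_p is not None and ints.tensors.ep is not None:
        F -= np.einsum("pqPQ,PQ->pq", ints.tensors.ep, density_p, optimize=True)
    return F


def build_nuclear_fock(
    density_p: np.ndarray,
    density_e: np.ndarray | None,
    ints: NEOIntegrals,
    n_quantum: int,
) -> np.ndarray:
    """F_p = T_p/m + V_p(classical; repulsive) + J_pp(D_p) - J_pe(D_e).

    Proton-proton Coulomb only exists between distinct quantum protons
    (no same-species exchange; a single proton has no J_pp at all).
    """
    F = ints.proton.core.copy()
    if n_quantum >= 2 and ints.tensors.pp is not None:
        F += _coulomb(ints.tensors.pp, density_p)
    if density_e is not None and ints.tensors.ep is not None:
        F -= np.einsum("pqPQ,pq->PQ", ints.tensors.ep, density_e, optimize=True)
    return F


def solve_roothaan(
    fock: np.ndarray,
    overlap: np.ndarray,
    n_occ: int,
    occupation: float = 1.0,
    lindep_threshold: float = 1e-10,
):
    """Generalized eigenproblem via canonical orthogonalization.

    Overlap eigenvectors with eigenvalue below ``lindep_threshold`` are
    projected out.  Returns (mo_coeffs, orbital_energies, density) with
    density = occupation * C_occ C_occ^T.
    """
    s, U = np.linalg.eigh(overlap)
    keep = s > lindep_threshold
    if not np.any(keep):
        raise np.linalg.LinAlgError(
            "all overlap eigenvalues below the linear-dependence threshold"
        )
    X = U[:, keep] / np.sqrt(s[keep])
    f = X.T @ fock @ X
    eps, V = np.linalg.eigh(f)
    C = X @ V
    if n_occ > C.shape[1]:
        raise ValueError("not enough independent basis functions for occupancy")
    occ = C[:, :n_occ]
    D = occupation * occ @ occ.T
    return C, eps, D


def total_energy(
    density_e: np.ndarray | None,
    density_p: np.ndarray | None,
    ints: NEOIntegrals,
    system: MolecularSystem,
    n_electrons: int,
) -> dict:
    """Energy decomposition of the product ansatz, hartree.

    The electron-proton coupling -Tr(D_e J_ep(D_p)) is counted once;
    the classical repulsion runs over classical nuclei only.
    """
    E_e = 0.0
    if density_e is not None and ints.electron is not None:
        E_e = float(np.einsum("pq,pq->", density_e, ints.electron.core))
        if n_electrons > 1:
            J = _coulomb(ints.tensors.ee, density_e)
            K = _exchange(ints.tensors.ee, density_e)
            E_e += 0.5 * float(np.einsum("pq,pq->", density_e, J - 0.5 * K))
    E_p = 0.0
    if density_p is not None and ints.proton is not None:
        E_p = float(np.einsum("PQ,PQ->", density_p, ints.proton.core))
        if ints.tensors.pp is not None and system.n_quantum >= 2:
            Jp = _coulomb(ints.tensors.pp, density_p)
            E_p += 0.5 * float(np.einsum("PQ,PQ->", density_p, Jp))
    E_c = 0.0
    if (
        density_e is not None
        and density_p is not None
        and ints.tensors.ep is not None
    ):
        E_c = -float(
            np.einsum(
                "pqPQ,pq,PQ->", ints.tensors.ep, density_e, density_p,
                optimize=True,
            )
        )
    E_cl = system.classical_repulsion()
    total = E_e + E_p + E_c + E_cl
    return {
        "E_electronic": E_e,
        "E_nuclear_quantum": E_p,
        "E_coupling": E_c,
        "E_classical_repulsion": E_cl,
        "E_total": total,
    }


class DIIS:
    """Pulay direct inversion in the iterative subspace for one species."""

    def __init__(self, depth: int = 10):
        self.depth = depth
        self.focks: list[np.ndarray] = []
        self.errors: list[np.ndarray] = []

    def push(self, fock: np.ndarray, error: np.ndarray) -> None:
        self.focks.append(fock.copy())
        self.errors.append(error.copy())
        if len(self.focks) > self.depth:
            self.focks.pop(0)
            self.errors.pop(0)

    def extrapolate(self) -> np.ndarray:
        n = len(self.focks)
        if n == 0:
            raise ValueError("empty DIIS history")
        if n == 1:
            return self.focks[0].copy()
        B = np.empty((n + 1, n + 1))
        B[-1, :] = -1.0
        B[:, -1] = -1.0
        B[-1, -1] = 0.0
        for i in range(n):
            for j in range(i, n):
                B[i, j] = B[j, i] = float(np.vdot(self.errors[i], self.errors[j]))
        rhs = np.zeros(n + 1)
        rhs[-1] = -1.0
        try:
            c = np.linalg.solve(B, rhs)
            if not np.all(np.isfinite(c)):
                raise np.linalg.LinAlgError("non-finite DIIS solution")
        except np.linalg.LinAlgError:
            c, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            if not np.all(np.isfinite(c)):
                log.warning("singular DIIS matrix; falling back to latest Fock")
                return self.focks[-1].copy()
        F = np.zeros_like(self.focks[0])
        for ci, Fi in zip(c[:-1], self.focks):
            F += ci * Fi
        return F


def _diis_error(F, D, S):
    return F @ D @ S - S @ D @ F


def _core_guess(ints: NEOIntegrals, species: str, n_occ, occupation, lindep):
    mats = ints.electron if species == "e" else ints.proton
    _, _, D = solve_roothaan(mats.core, mats.overlap, n_occ, occupation, lindep)
    return D


def run_neo_scf(
    system: MolecularSystem,
    basis_e: BasisSet,
    basis_p: BasisSet | None = None,
    settings: ConvergenceSettings | None = None,
    *,
    integrals: NEOIntegrals | None = None,
    initial_densities: tuple | None = None,
    post_nuclear_hook=None,
    max_memory_mb: float = 2000.0,
):
    """Run the stepwise coupled SCF to global convergence.

    Returns ``(SCFState, MolecularSystem, NEOIntegrals)``; the returned
    system/integrals differ from the input ones when ``post_nuclear_hook``
    moved quantum centers.  The hook runs after each converged nuclear
    subcycle as ``hook(state, system, integrals)`` and returns
    ``(system, integrals, max_displacement_bohr)``.
    """
    settings = settings or ConvergenceSettings()
    n_e = system.n_electrons
    n_q = system.n_quantum
    if basis_p is None and n_q:
        raise ValueError("quantum centers present but no proton basis given")
    occ_e = 1 if n_e == 1 else n_e // 2
    fac_e = 1.0 if n_e == 1 else 2.0
    ints = integrals or compute_integrals(system, basis_e, basis_p, max_memory_mb)

    state = SCFState()
    if initial_densities is not None:
        state.density_e, state.density_p = initial_densities
    if state.density_e is None and n_e:
        state.density_e = _core_guess(ints, "e", occ_e, fac_e, settings.lindep_threshold)
    if state.density_p is None and n_q:
        state.density_p = _core_guess(ints, "p", n_q, 1.0, settings.lindep_threshold)

    log_rows = state.iteration_log
    disp = 0.0
    sub_ok_p = n_q == 0
    sub_ok_e = n_e == 0
    E_prev = total_energy(state.density_e, state.density_p, ints, system, n_e)[
        "E_total"
    ]
    E_running = E_prev

    for macro in range(1, settings.max_macrocycles + 1):
        state.n_macrocycles = macro
        if n_q:
            sub_ok_p, E_running = _species_cycle(
                "nuclear", macro, state, ints, system, settings,
                n_e, n_q, occ_e, fac_e, E_running, log_rows,
            )
        if post_nuclear_hook is not None:
            system, ints, disp = post_nuclear_hook(state, system, ints)
        if n_e:
            sub_ok_e, E_running = _species_cycle(
                "electronic", macro, state, ints, system, settings,
                n_e, n_q, occ_e, fac_e, E_running, log_rows,
            )
        comps = total_energy(state.density_e, state.density_p, ints, system, n_e)
        E_now = comps["E_total"]
        dE_macro = E_now - E_prev if (macro > 1 or not (n_q or n_e)) else np.inf
        E_prev = E_now
        E_running = E_now
        log_rows.append(
            {
                "level": "macro",
                "macro": macro,
                "iter": macro,
                "E_total": E_now,
                "dE": dE_macro,
                "drms": np.nan,
                "gnorm": np.nan,
                "displacement": disp,
            }
        )
        log.info(
            "macro %3d  E=%.10f  dE=%.3e  disp=%.3e",
            macro, E_now, dE_macro, disp,
        )
        pos_ok = post_nuclear_hook is None or disp < getattr(
            post_nuclear_hook, "position_threshold", 1e-5
        )
        if abs(dE_macro) < settings.neo_e_conv and sub_ok_p and sub_ok_e and pos_ok:
            state.converged = True
            break

    state.energy_components = total_energy(
        state.density_e, state.density_p, ints, system, n_e
    )
    if not state.converged:
        raise SCFConvergenceError(
            f"NEO-SCF did not converge in {settings.max_macrocycles} macrocycles"
            + (
                "; oscillating centroid updates can be tamed with "
                "damping_factor < 1"
                if post_nuclear_hook is not None
                else ""
            ),
            iteration_log=log_rows,
        )
    return state, system, ints


def _species_cycle(
    level, macro, state, ints, system, settings,
    n_e, n_q, occ_e, fac_e, E_in, log_rows,
):
    """Converge one species' Roothaan-Hall subproblem with DIIS."""
    is_p = level == "nuclear"
    diis = DIIS(settings.diis_depth)
    maxit = settings.max_nuclear_cycles if is_p else settings.max_electronic_cycles
    S = (ints.proton if is_p else ints.electron).overlap
    E_old = E_in
    ok = False
    for it in range(1, maxit + 1):
        if is_p:
            F = build_nuclear_fock(state.density_p, state.density_e, ints, n_q)
            D_old = state.density_p
        else:
            F = build_electronic_fock(state.density_e, state.density_p, ints, n_e)
            D_old = state.density_e
        err = _diis_error(F, D_old, S)
        gnorm = float(np.linalg.norm(err))
        diis.push(F, err)
        F_use = diis.extrapolate() if it > settings.diis_start else F
        C, eps, D_new = solve_roothaan(
            F_use, S,
            n_q if is_p else occ_e,
            1.0 if is_p else fac_e,
            settings.lindep_threshold,
        )
        if is_p:
            state.density_p, state.mo_coeffs_p = D_new, C
            state.orbital_energies_p, state.fock_p = eps, F
        else:
            state.density_e, state.mo_coeffs_e = D_new, C
            state.orbital_energies_e, state.fock_e = eps, F
        comps = total_energy(state.density_e, state.density_p, ints, system, n_e)
        E_new = comps["E_total"]
        dE = E_new - E_old
        drms = float(np.sqrt(np.mean((D_new - D_old) ** 2)))
        log_rows.append(
            {
                "level": level,
                "macro": macro,
                "iter": it,
                "E_total": E_new,
                "dE": dE,
                "drms": drms,
                "gnorm": gnorm,
                "displacement": np.nan,
            }
        )
        log.debug(
            "%s %2d.%02d  E=%.10f dE=%.2e drms=%.2e g=%.2e",
            level, macro, it, E_new, dE, drms, gnorm,
        )
        E_old = E_new
        if abs(dE) < settings.e_conv and drms < settings.d_conv and gnorm < settings.g_conv:
            ok = True
            break
    return ok, E_old


def write_log_csv(iteration_log: list, path) -> None:
    """Machine-readable per-iteration log (one row per cycle)."""
    import pandas as pd

    pd.DataFrame(iteration_log).to_csv(path, index=False)
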