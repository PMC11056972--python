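"""Numerical-gradient optimization of quantum-center positions and PES scans.

The energy here is the *extended* NEO surface E(r_q): a full coupled SCF at
fixed quantum-center placements.  Minimizing it with central-difference
gradients yields the standard NEO surface point — the independent oracle
against which the adaptive centroid procedure is validated.  Displaced SCFs
are warm-started from the reference densities, which is what makes the
finite differences affordable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .basis import BasisSet
from .molsys import MolecularSystem
from .scf import ConvergenceSettings, SCFConvergenceError, run_neo_scf
from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

__all__ = [
    "PESScan",
    "OptResult",
    "extended_pes_energy",
    "numerical_gradient",
    "optimize_rq",
    "scan_1d",
]

log = logging.getLogger(__name__)

#: tight SCF used inside gradient evaluations so finite-difference noise
#: stays well below the optimizer's thresholds
_TIGHT = ConvergenceSettings(
    e_conv=1e-10, d_conv=1e-10, g_conv=1e-10, neo_e_conv=1e-9
)


@dataclass
class OptResult:
    """Outcome of the gradient-based quantum-center optimization."""

    optimal_rq: np.ndarray  # (n_q, 3) Bohr
    e_min: float
    n_energy_evaluations: int
    converged: bool
    gradient_norm: float = np.nan


@dataclass
class PESScan:
    """1-D rigid scan of one quantum center along an axis.

    ``grid`` holds signed displacements in Angstrom from the reference
    position; ``energies_neo`` is the extended-NEO energy with r_q pinned
    at each point, ``energies_rhf`` (optional) the conventional HF energy
    with the proton as a classical nucleus at the same point.
    """

    axis: np.ndarray
    grid: np.ndarray
    energies_neo: np.ndarray
    energies_rhf: np.ndarray | None
    centroid_at_point: np.ndarray  # (n, 3) Bohr, NaN where SCF failed
    base_position: np.ndarray      # Bohr

    def to_frame(self):
        import pandas as pd

        data = {
            "displacement_angstrom": self.grid,
            "E_neo_hartree": self.energies_neo,
            "centroid_axis_angstrom": (
                (self.centroid_at_point - self.base_position) @ self.axis
            )
            * ANGSTROM_PER_BOHR,
        }
        if self.energies_rhf is not None:
            data["E_rhf_hartree"] = self.energies_rhf
        return pd.DataFrame(data)

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def minimum_neo(self) -> float:
        """Grid displacement (Angstrom) of the lowest extended-NEO energy."""
        return float(self.grid[np.nanargmin(self.energies_neo)])

    def minimum_rhf(self) -> float:
        if self.energies_rhf is None:
            raise ValueError("scan was run without the conventional-HF curve")
        return float(self.grid[np.nanargmin(self.energies_rhf)])


class _EnergyFunction:
    """E(r_q) with converged-density warm starts and an evaluation counter."""

    def __init__(self, system, basis_e, basis_p, settings=None, max_memory_mb=2000.0):
        self.system = system
        self.basis_e = basis_e
        self.basis_p = basis_p
        self.settings = settings or _TIGHT
        self.max_memory_mb = max_memory_mb
        self.qidx = list(system.quantum_indices)
        self.densities = None
        self.n_evaluations = 0

    def positions_to_x(self, system=None) -> np.ndarray:
        system = system or self.system
        return np.concatenate(
            [system.centers[i].position for i in self.qidx]
        )

    def system_at(self, x: np.ndarray) -> MolecularSystem:
        pos = self.system.positions()
        for k, qc in enumerate(self.qidx):
            pos[qc] = x[3 * k : 3 * k + 3]
        return self.system.with_positions(pos)

    def __call__(self, x: np.ndarray) -> float:
        sysx = self.system_at(np.asarray(x, dtype=float))
        try:
            state, _, _ = run_neo_scf(
                sysx, self.basis_e, self.basis_p, self.settings,
                initial_densities=self.densities,
                max_memory_mb=self.max_memory_mb,
            )
        except SCFConvergenceError as exc:
            raise SCFConvergenceError(
                f"SCF failed at displaced point r_q={x!r}",
                iteration_log=exc.iteration_log,
            ) from exc
        self.densities = (state.density_e, state.density_p)
        self.n_evaluations += 1
        return state.e_total


def extended_pes_energy(
    system: MolecularSystem,
    basis_e: BasisSet,
    basis_p: BasisSet,
    settings: ConvergenceSettings | None = None,
) -> float:
    """One point of the extended NEO PES (fixed r_q, fully converged SCF)."""
    f = _EnergyFunction(system, basis_e, basis_p, settings)
    return f(f.positions_to_x())


def numerical_gradient(
    system: MolecularSystem,
    basis_e: BasisSet,
    basis_p: BasisSet,
    step: float = 1e-3,
    energy_fn: _EnergyFunction | None = None,
) -> np.ndarray:
    """Central-difference gradient dE/dr_q, hartree/Bohr, shape (n_q, 3).

    Every displaced point is a fully converged coupled SCF.
    """
    if step <= 0:
        raise ValueError("finite-difference step must be positive")
    f = energy_fn or _EnergyFunction(system, basis_e, basis_p)
    x0 = f.positions_to_x(system)
    g = np.empty_like(x0)
    for i in range(len(x0)):
        xp = x0.copy()
        xp[i] += step
        xm = x0.copy()
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2.0 * step)
    return g.reshape(-1, 3)


def optimize_rq(
    system: MolecularSystem,
    basis_e: BasisSet,
    basis_p: BasisSet,
    *,
    gtol: float = 1e-5,
    step: float = 1e-3,
    max_evaluations: int = 400,
    settings: ConvergenceSettings | None = None,
) -> OptResult:
    """Quasi-Newton (BFGS) minimization of E(r_q) with numerical gradients.

    Converged at gradient norm < ``gtol`` hartree/Bohr; classical centers
    stay frozen throughout.
    """
    f = _EnergyFunction(system, basis_e, basis_p, settings)
    x0 = f.positions_to_x()

    def jac(x):
        return numerical_gradient(
            f.system_at(x), basis_e, basis_p, step, energy_fn=f
        ).ravel()

    res = scipy.optimize.minimize(
        f, x0, jac=jac, method="BFGS",
        options={"gtol": gtol, "maxiter": max_evaluations, "norm": 2},
    )
    return OptResult(
        optimal_rq=res.x.reshape(-1, 3),
        e_min=float(res.fun),
        n_energy_evaluations=f.n_evaluations,
        converged=bool(res.success),
        gradient_norm=float(np.linalg.norm(res.jac)),
    )


def scan_1d(
    system: MolecularSystem,
    basis_e: BasisSet,
    basis_p: BasisSet,
    center_index: int,
    axis,
    grid,
    *,
    include_rhf: bool = True,
    settings: ConvergenceSettings | None = None,
) -> PESScan:
    """Rigid 1-D scan of one quantum center (grid in Angstrom).

    At every grid point the extended-NEO energy is converged with r_q
    pinned there; optionally a conventional restricted-HF curve is computed
    with the proton demoted to a classical point charge at the same spot.
    Per-point SCF failures are recorded as NaN and the scan continues.
    """
    from dataclasses import replace as _replace

    from .adaptive import assign_orbitals, compute_centroids
    from .scf import compute_integrals

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid displacements must be strictly increasing")
    if np.max(np.abs(grid)) > 1.0 + 1e-12:
        raise ValueError("scan window limited to +-1 Angstrom")
    if not system.centers[center_index].is_quantum:
        raise ValueError("scanned center must be quantum")
    settings = settings or ConvergenceSettings()
    base = system.centers[center_index].position.copy()

    e_neo = np.full(len(grid), np.nan)
    e_rhf = np.full(len(grid), np.nan) if include_rhf else None
    centroids = np.full((len(grid), 3), np.nan)

    classical_system = None
    if include_rhf:
        classical_system = MolecularSystem(
            tuple(
                _replace(c, is_quantum=False) for c in system.centers
            ),
            system.total_charge,
        )

    dens_neo = None
    dens_rhf = None
    for i, d in enumerate(grid):
        target = base + d * BOHR_PER_ANGSTROM * axis
        sys_i = system.move_center(center_index, target)
        try:
            state, _, ints = run_neo_scf(
                sys_i, basis_e, basis_p, settings,
                initial_densities=dens_neo,
            )
            dens_neo = (state.density_e, state.density_p)
            e_neo[i] = state.e_total
            assignment = assign_orbitals(
                state, basis_p, sys_i, ints.proton.overlap
            )
            cen = compute_centroids(state, ints.proton, assignment)
            k = list(sys_i.quantum_indices).index(center_index)
            centroids[i] = cen[k]
        except SCFConvergenceError:
            log.warning("NEO SCF failed at grid point %g A; marked missing", d)
            dens_neo = None
        if include_rhf:
            csys = classical_system.move_center(center_index, target)
            try:
                st, _, _ = run_neo_scf(
                    csys, basis_e, None, settings,
                    initial_densities=dens_rhf,
                )
                dens_rhf = (st.density_e, st.density_p)
                e_rhf[i] = st.e_total
            except SCFConvergenceError:
                log.warning(
                    "RHF failed at grid point %g A; marked missing", d
                )
                dens_rhf = None
    return PESScan(
        axis=axis,
        grid=grid,
        energies_neo=e_neo,
        energies_rhf=e_rhf,
        centroid_at_point=centroids,
        base_position=base,
    )
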