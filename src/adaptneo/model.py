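"""Model/Results interface over the coupled electron-proton SCF machinery.

:class:`NEOHartreeFock` is constructed from a molecular system plus basis
specifications; :meth:`~NEOHartreeFock.fit` runs either a plain coupled SCF
(``adaptive=False``, the extended-PES point at the given quantum-center
positions) or the adaptive centroid procedure (the default), and returns a
:class:`NEOResults` carrying the converged state, energy decomposition,
final geometry, per-iteration log and — for adaptive fits — the centroid
trace.  Scans and gradient-based optimization hang off the model.
"""

from __future__ import annotations

import io

import numpy as np

from .adaptive import AdaptiveSettings, AdaptiveTrace, run_adaptive_neo
from .basis import BasisSet, load_basis
from .molsys import MolecularSystem, write_xyz
from .optimize import OptResult, PESScan, numerical_gradient, optimize_rq, scan_1d
from .scf import ConvergenceSettings, SCFState, run_neo_scf
from .units import ANGSTROM_PER_BOHR, HARTREE_TO_KCALMOL

__all__ = ["NEOHartreeFock", "NEOResults"]


class NEOHartreeFock:
    """Coupled electron-proton restricted Hartree-Fock model for one system.

    Parameters
    ----------
    system:
        Molecular system with its quantum/classical center partition.
    basis_e, basis_p:
        Basis names/paths (resolved with :func:`~adaptneo.basis.load_basis`)
        or ready :class:`~adaptneo.basis.BasisSet` objects.  ``basis_p`` may
        be omitted for systems without quantum centers.
    settings, adaptive_settings:
        SCF and centroid-update thresholds; defaults reproduce the
        documented convergence criteria (1e-8 au subcycles, 1e-6 hartree
        macrocycles, 1e-5 Bohr positions).
    """

    def __init__(
        self,
        system: MolecularSystem,
        basis_e,
        basis_p=None,
        settings: ConvergenceSettings | None = None,
        adaptive_settings: AdaptiveSettings | None = None,
    ):
        self.system = system
        self.basis_e = (
            basis_e
            if isinstance(basis_e, BasisSet)
            else load_basis(basis_e, "electron", system)
        )
        if basis_p is None and system.n_quantum:
            raise ValueError("system has quantum centers: basis_p is required")
        self.basis_p = (
            basis_p
            if (basis_p is None or isinstance(basis_p, BasisSet))
            else load_basis(basis_p, "proton", system)
        )
        self.settings = settings or ConvergenceSettings()
        self.adaptive_settings = adaptive_settings or AdaptiveSettings()

    @classmethod
    def from_xyz(
        cls, path, quantum_atoms=(), charge=0, basis_e="sto-3g",
        basis_p="et-6s3p", **kwargs,
    ) -> "NEOHartreeFock":
        from .molsys import read_xyz

        system = read_xyz(path, quantum_atoms, charge)
        return cls(
            system, basis_e,
            basis_p if system.n_quantum else None,
            **kwargs,
        )

    def fit(self, adaptive: bool | None = None) -> "NEOResults":
        """Converge the coupled SCF; with ``adaptive=True`` (default when
        quantum centers exist) relocate the centers to their centroids."""
        if adaptive is None:
            adaptive = self.system.n_quantum > 0
        if adaptive:
            state, final_system, trace = run_adaptive_neo(
                self.system, self.basis_e, self.basis_p,
                self.settings, self.adaptive_settings,
            )
        else:
            state, final_system, _ = run_neo_scf(
                self.system, self.basis_e, self.basis_p, self.settings
            )
            trace = None
        return NEOResults(self, state, final_system, trace, adaptive)

    def optimize(self, **kwargs) -> OptResult:
        """Gradient-based (numerical) optimization of the quantum centers —
        the independent oracle for the adaptive fit."""
        return optimize_rq(self.system, self.basis_e, self.basis_p, **kwargs)

    def gradient(self, step: float = 1e-3) -> np.ndarray:
        return numerical_gradient(
            self.system, self.basis_e, self.basis_p, step
        )

    def scan(self, center_index, axis, grid, **kwargs) -> PESScan:
        """1-D extended-NEO (and optionally conventional-HF) PES scan."""
        return scan_1d(
            self.system, self.basis_e, self.basis_p, center_index, axis,
            grid, **kwargs,
        )


class NEOResults:
    """Converged coupled-SCF results.

    Attributes
    ----------
    state : SCFState
        Densities, Fock matrices, orbitals and orbital energies.
    system : MolecularSystem
        Final geometry (quantum centers at their converged positions for
        adaptive fits).
    trace : AdaptiveTrace | None
        Per-macrocycle centroid history (adaptive fits only).
    """

    def __init__(
        self,
        model: NEOHartreeFock,
        state: SCFState,
        system: MolecularSystem,
        trace: AdaptiveTrace | None,
        adaptive: bool,
    ):
        self.model = model
        self.state = state
        self.system = system
        self.trace = trace
        self.adaptive = adaptive

    @property
    def e_total(self) -> float:
        return self.state.e_total

    @property
    def energy_components(self) -> dict:
        return self.state.energy_components

    @property
    def converged(self) -> bool:
        return self.state.converged

    @property
    def quantum_positions(self) -> np.ndarray:
        """Converged quantum-center positions, (n_q, 3) Bohr."""
        return np.array(
            [self.system.centers[i].position for i in self.system.quantum_indices]
        )

    def iteration_frame(self):
        import pandas as pd

        return pd.DataFrame(self.state.iteration_log)

    def write_xyz(self, path, comment=""):
        write_xyz(self.system, path, comment)

    def energy_report(self) -> dict:
        """Energy decomposition in hartree and kcal/mol."""
        comps = self.state.energy_components
        return {
            k: {
                "hartree": float(v),
                "kcal_per_mol": float(v) * HARTREE_TO_KCALMOL,
            }
            for k, v in comps.items()
        }

    def summary(self) -> str:
        comps = self.state.energy_components
        n_iter = sum(
            1 for r in self.state.iteration_log if r["level"] != "macro"
        )
        buf = io.StringIO()
        w = buf.write
        mode = "adaptive NEO-RHF" if self.adaptive else (
            "NEO-RHF" if self.system.n_quantum else "RHF"
        )
        w(f"{'':=^66}\n")
        w(f"{mode + ' results':^66}\n")
        w(f"{'':=^66}\n")
        w(f"centers: {len(self.system.centers)}  "
          f"(quantum: {self.system.n_quantum})   "
          f"electrons: {self.system.n_electrons}   "
          f"charge: {self.system.total_charge:+d}\n")
        w(f"basis functions: {self.model.basis_e.n_functions} electronic"
          + (
              f", {self.model.basis_p.n_functions} protonic"
              if self.model.basis_p is not None
              else ""
          )
          + "\n")
        w(f"converged: {self.state.converged}   macrocycles: "
          f"{self.state.n_macrocycles}   total SCF iterations: {n_iter}\n")
        w(f"{'':-^66}\n")
        w(f"{'component':<28}{'hartree':>18}{'kcal/mol':>20}\n")
        for k, v in comps.items():
            w(f"{k:<28}{v:>18.10f}{v * HARTREE_TO_KCALMOL:>20.4f}\n")
        w(f"{'':-^66}\n")
        if self.adaptive and self.trace is not None and self.trace.macrocycle:
            w("quantum-center positions (Angstrom):\n")
            for i, qi in enumerate(self.system.quantum_indices):
                x, y, z = self.system.centers[qi].position * ANGSTROM_PER_BOHR
                w(f"  center {qi:<3d} {x:>12.6f} {y:>12.6f} {z:>12.6f}\n")
            w(
                f"final centroid displacement: "
                f"{self.trace.final_displacement:.2e} Bohr "
                f"in {len(self.trace.macrocycle)} updates\n"
            )
        w(f"{'':=^66}\n")
        return buf.getvalue()
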