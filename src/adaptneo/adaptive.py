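"""Adaptive relocation of quantum centers to proton charge centroids.

After each converged nuclear subcycle the expectation value <phi_i|r|phi_i>
of every occupied nuclear orbital is computed; each orbital is mapped
one-to-one to a quantum center (optimal Mulliken-population matching) and
the center — carrying its protonic *and* electronic basis functions — is
moved to the centroid (optionally damped).  All position-dependent
integrals are rebuilt and the SCF continues, so the procedure converges to
the optimal basis-center placement without any gradient evaluation: a
fixed-point iteration on the centroid map, certified externally by the
numerical-gradient optimizer in :mod:`.optimize`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .basis import BasisSet
from .molsys import MolecularSystem
from .scf import (
    ConvergenceSettings,
    NEOIntegrals,
    SCFState,
    compute_integrals,
    run_neo_scf,
    total_energy,
)

__all__ = [
    "AdaptiveSettings",
    "AdaptiveTrace",
    "compute_centroids",
    "assign_orbitals",
    "adaptive_step",
    "run_adaptive_neo",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdaptiveSettings:
    """Controls of the centroid update.

    ``position_threshold`` (Bohr) is the convergence criterion on the
    largest centroid displacement; ``damping_factor`` scales each step
    (1 = undamped, the default — damping exists to quench oscillations).
    """

    position_threshold: float = 1e-5
    damping_factor: float = 1.0
    max_step: float = 1.0  # runaway guard, Bohr

    def __post_init__(self):
        if self.position_threshold <= 0:
            raise ValueError("position_threshold must be positive")
        if not (0.0 < self.damping_factor <= 1.0):
            raise ValueError("damping_factor must lie in (0, 1]")


@dataclass
class AdaptiveTrace:
    """Per-macrocycle history of the adaptive procedure."""

    macrocycle: list = field(default_factory=list)
    centroids: list = field(default_factory=list)      # (n_q, 3) Bohr
    positions: list = field(default_factory=list)      # r_q after update
    displacements: list = field(default_factory=list)  # max |step| Bohr
    energies: list = field(default_factory=list)
    components: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for k, m in enumerate(self.macrocycle):
            for c, (cen, pos) in enumerate(
                zip(self.centroids[k], self.positions[k])
            ):
                rows.append(
                    {
                        "macrocycle": m,
                        "center": c,
                        "x": pos[0],
                        "y": pos[1],
                        "z": pos[2],
                        "centroid_x": cen[0],
                        "centroid_y": cen[1],
                        "centroid_z": cen[2],
                        "step_norm": self.displacements[k],
                        "E_total": self.energies[k],
                        **{
                            key: self.components[k][key]
                            for key in (
                                "E_electronic",
                                "E_nuclear_quantum",
                                "E_coupling",
                                "E_classical_repulsion",
                            )
                        },
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @property
    def final_displacement(self) -> float:
        return self.displacements[-1] if self.displacements else np.nan


def compute_centroids(
    state: SCFState,
    position_matrices,
    assignment: list[int] | np.ndarray,
) -> np.ndarray:
    """Charge centroids <phi_i|r|phi_i> of the assigned nuclear orbitals.

    ``assignment[k]`` is the occupied-orbital column (of ``mo_coeffs_p``)
    mapped to the k-th quantum center; returns (n_q, 3) in Bohr.
    """
    C = state.mo_coeffs_p
    if C is None:
        raise ValueError("no nuclear orbitals available")
    R = (
        position_matrices.position()
        if hasattr(position_matrices, "position")
        else np.asarray(position_matrices)
    )
    out = np.empty((len(assignment), 3))
    for k, orb in enumerate(assignment):
        c = C[:, orb]
        for d in range(3):
            out[k, d] = c @ R[d] @ c
    return out


def assign_orbitals(
    state: SCFState,
    basis_p: BasisSet,
    system: MolecularSystem,
    overlap_p: np.ndarray,
) -> list[int]:
    """One-to-one map quantum center -> occupied nuclear orbital.

    The assignment maximizes the summed per-center Mulliken populations
    (optimal bipartite matching); with equally optimal matchings the
    lowest center index wins the lower orbital.  Orbitals whose best
    population falls below 0.5 trigger an ambiguity warning.
    """
    qcenters = list(system.quantum_indices)
    n_q = len(qcenters)
    C = state.mo_coeffs_p
    if C is None or C.shape[1] < n_q:
        raise ValueError("need one occupied nuclear orbital per quantum center")
    ao_center = np.repeat(
        [sh.center_index for sh in basis_p.shells],
        [sh.n_sph for sh in basis_p.shells],
    )
    pop = np.zeros((n_q, n_q))  # [center, orbital]
    for orb in range(n_q):
        c = C[:, orb]
        mull = (np.outer(c, c) * overlap_p).sum(axis=1)
        for k, qc in enumerate(qcenters):
            pop[k, orb] = mull[ao_center == qc].sum()
    row, col = linear_sum_assignment(-pop)
    assignment = [int(c) for _, c in sorted(zip(row, col))]
    for k in range(n_q):
        if pop[k, assignment[k]] < 0.5:
            log.warning(
                "ambiguous orbital assignment: center %d gets orbital %d with "
                "Mulliken population %.3f < 0.5",
                qcenters[k], assignment[k], pop[k, assignment[k]],
            )
    return assignment


def adaptive_step(
    state: SCFState,
    system: MolecularSystem,
    basis_e: BasisSet,
    basis_p: BasisSet,
    settings: AdaptiveSettings,
    ints: NEOIntegrals,
    max_memory_mb: float = 2000.0,
):
    """Move quantum centers toward their centroids and rebuild integrals.

    Returns ``(system, integrals, max_displacement, centroids)``.  Both the
    protonic shells and the moved center's electronic shells follow, since
    they reference the same center.  Classical centers never move.
    """
    assignment = assign_orbitals(state, basis_p, system, ints.proton.overlap)
    centroids = compute_centroids(state, ints.proton, assignment)
    qidx = list(system.quantum_indices)
    pos = system.positions()
    max_disp = 0.0
    for k, qc in enumerate(qidx):
        step = settings.damping_factor * (centroids[k] - pos[qc])
        norm = float(np.linalg.norm(step))
        if norm > settings.max_step:
            raise RuntimeError(
                f"runaway adaptive step of {norm:.3f} Bohr at center {qc}; "
                "the starting geometry is likely far outside the basin"
            )
        pos[qc] = pos[qc] + step
        max_disp = max(max_disp, norm)
    if max_disp < 1e-14:  # numerically at the fixed point: nothing to rebuild
        return system, ints, max_disp, centroids
    system = system.with_positions(pos)
    ints = compute_integrals(system, basis_e, basis_p, max_memory_mb)
    return system, ints, max_disp, centroids


def run_adaptive_neo(
    system: MolecularSystem,
    basis_e: BasisSet,
    basis_p: BasisSet,
    scf_settings: ConvergenceSettings | None = None,
    adaptive_settings: AdaptiveSettings | None = None,
    *,
    initial_densities: tuple | None = None,
    max_memory_mb: float = 2000.0,
):
    """Coupled SCF with in-cycle centroid relocation (the adaptive method).

    Converged when the SCF energy/density/gradient criteria *and* the
    centroid-displacement criterion are all satisfied.  Returns
    ``(SCFState, MolecularSystem, AdaptiveTrace)`` with the final system
    holding the converged quantum-center positions on the standard NEO
    potential-energy surface.
    """
    if system.n_quantum == 0:
        raise ValueError("adaptive procedure needs at least one quantum center")
    scf_settings = scf_settings or ConvergenceSettings()
    aset = adaptive_settings or AdaptiveSettings()
    trace = AdaptiveTrace()

    def hook(state, sys_now, ints_now):
        sys_new, ints_new, disp, centroids = adaptive_step(
            state, sys_now, basis_e, basis_p, aset, ints_now, max_memory_mb
        )
        comps = total_energy(
            state.density_e, state.density_p, ints_new, sys_new,
            sys_new.n_electrons,
        )
        trace.macrocycle.append(len(trace.macrocycle) + 1)
        trace.centroids.append(centroids.copy())
        trace.positions.append(
            np.array(
                [sys_new.centers[i].position for i in sys_new.quantum_indices]
            )
        )
        trace.displacements.append(disp)
        trace.energies.append(comps["E_total"])
        trace.components.append(comps)
        return sys_new, ints_new, disp

    hook.position_threshold = aset.position_threshold
    state, final_system, _ = run_neo_scf(
        system, basis_e, basis_p, scf_settings,
        initial_densities=initial_densities,
        post_nuclear_hook=hook,
        max_memory_mb=max_memory_mb,
    )
    return state, final_system, trace
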