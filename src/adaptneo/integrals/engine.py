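"""Integral backend contract: matrices and tensors over movable centers.

Any engine exposing this surface (overlap/kinetic/point-charge/position
one-particle matrices and same-/cross-species Coulomb tensors over shells)
can stand behind the SCF; the bundled backend is a McMurchie-Davidson
implementation in :mod:`._md`.  All quantities are rebuilt from the
*current* center positions on every call, so an adaptive move of a quantum
center is reflected exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from . import _md

if TYPE_CHECKING:  # avoid a circular import; only needed for annotations
    from ..basis import BasisSet
    from ..molsys import MolecularSystem
from .spherical import cart_components, n_cart, transform_matrix

__all__ = [
    "OneParticleMatrices",
    "TwoParticleTensors",
    "one_particle",
    "two_particle",
    "overlap_pair",
]


@dataclass
class OneParticleMatrices:
    """One-particle integrals of a species over its spherical AO basis.

    ``kinetic`` is already divided by the particle mass (i.e. it is
    <-grad^2/(2m)>); ``point_charge`` carries the species' sign
    (attractive, negative, for electrons; repulsive for protons).
    """

    overlap: np.ndarray
    kinetic: np.ndarray
    point_charge: np.ndarray
    position_x: np.ndarray
    position_y: np.ndarray
    position_z: np.ndarray

    @property
    def core(self) -> np.ndarray:
        return self.kinetic + self.point_charge

    def position(self) -> np.ndarray:
        """(3, n, n) stack of the Cartesian position-operator matrices."""
        return np.stack([self.position_x, self.position_y, self.position_z])


@dataclass
class TwoParticleTensors:
    """Coulomb tensors with positive kernels; signs live in the Fock builds.

    ``ee``: electron repulsion (chemist notation (mu nu|la si));
    ``pp``: proton-proton Coulomb, present only with >= 2 quantum protons;
    ``ep``: electron-proton cross Coulomb, (mu nu|P Q).
    """

    ee: np.ndarray | None = None
    pp: np.ndarray | None = None
    ep: np.ndarray | None = None


class _FlatBasis:
    """Flattened shell arrays + Cartesian->spherical transform for numba."""

    def __init__(self, basis: BasisSet, system: MolecularSystem):
        shells = basis.shells
        nsh = len(shells)
        self.sh_l = np.array([sh.angular_momentum for sh in shells], dtype=np.int64)
        self.sh_coord = np.array(
            [system.centers[sh.center_index].position for sh in shells]
        ).reshape(nsh, 3)
        nprim = [len(sh.exponents) for sh in shells]
        self.sh_nprim = np.array(nprim, dtype=np.int64)
        self.sh_pstart = np.concatenate(
            [[0], np.cumsum(nprim)]
        ).astype(np.int64)[:-1]
        self.prim_exp = np.array(
            [e for sh in shells for e in sh.exponents], dtype=float
        )
        self.prim_w = np.concatenate(
            [sh.weights() for sh in shells]
        ) if shells else np.zeros(0)
        ncart = [n_cart(sh.angular_momentum) for sh in shells]
        self.sh_cstart = np.concatenate([[0], np.cumsum(ncart)]).astype(np.int64)[:-1]
        self.ncart_total = int(sum(ncart))
        lx, ly, lz = [], [], []
        for sh in shells:
            for c in cart_components(sh.angular_momentum):
                lx.append(c[0])
                ly.append(c[1])
                lz.append(c[2])
        self.cart_lx = np.array(lx, dtype=np.int64)
        self.cart_ly = np.array(ly, dtype=np.int64)
        self.cart_lz = np.array(lz, dtype=np.int64)
        # block-diagonal cart -> sph transform
        self.n_sph = basis.n_functions
        T = np.zeros((self.ncart_total, self.n_sph))
        crow = 0
        scol = 0
        for sh in shells:
            tl = transform_matrix(sh.angular_momentum)
            T[crow : crow + tl.shape[0], scol : scol + tl.shape[1]] = tl
            crow += tl.shape[0]
            scol += tl.shape[1]
        self.T = T

    def pairs(self):
        return _md.build_pairs(
            self.sh_l, self.sh_coord, self.sh_pstart, self.sh_nprim,
            self.prim_exp, self.prim_w,
        )


def one_particle(basis: BasisSet, system: MolecularSystem) -> OneParticleMatrices:
    """Overlap, kinetic (mass-scaled), signed point-charge and position
    matrices for one species at the system's current geometry."""
    basis.validate_against(system)
    fb = _FlatBasis(basis, system)
    n = fb.ncart_total
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    MX = np.zeros((n, n))
    MY = np.zeros((n, n))
    MZ = np.zeros((n, n))
    pc_pos, pc_chg = system.point_charges()
    if len(basis.shells):
        _md.one_particle_cart(
            fb.sh_l, fb.sh_coord, fb.sh_pstart, fb.sh_nprim,
            fb.prim_exp, fb.prim_w,
            fb.sh_cstart, fb.cart_lx, fb.cart_ly, fb.cart_lz,
            np.ascontiguousarray(pc_pos.reshape(-1, 3)),
            np.ascontiguousarray(pc_chg),
            S, T, V, MX, MY, MZ,
        )
    sign = -1.0 if basis.species == "electron" else +1.0

    def tr(M):
        return fb.T.T @ M @ fb.T

    return OneParticleMatrices(
        overlap=tr(S),
        kinetic=tr(T) / basis.particle_mass,
        point_charge=sign * tr(V),
        position_x=tr(MX),
        position_y=tr(MY),
        position_z=tr(MZ),
    )


def _eri(fb1: _FlatBasis, fb2: _FlatBasis, same: bool) -> np.ndarray:
    p1 = fb1.pairs()
    p2 = p1 if same else fb2.pairs()
    out = np.zeros(
        (fb1.ncart_total, fb1.ncart_total, fb2.ncart_total, fb2.ncart_total)
    )
    _md.eri_cart(
        fb1.sh_l, fb1.sh_cstart, fb1.cart_lx, fb1.cart_ly, fb1.cart_lz,
        p1[0], p1[1], p1[2], p1[3], p1[4],
        fb2.sh_l, fb2.sh_cstart, fb2.cart_lx, fb2.cart_ly, fb2.cart_lz,
        p2[0], p2[1], p2[2], p2[3], p2[4],
        1 if same else 0,
        out,
    )
    # cart -> sph on all four indices
    out = np.tensordot(fb1.T, out, axes=(0, 0))          # i,q,r,s
    out = np.tensordot(fb1.T, out, axes=(0, 1))          # j,i,r,s
    out = np.tensordot(fb2.T, out, axes=(0, 2))          # k,j,i,s
    out = np.tensordot(fb2.T, out, axes=(0, 3))          # l,k,j,i
    return out.transpose(3, 2, 1, 0)


def two_particle(
    basis_e: BasisSet,
    basis_p: BasisSet | None,
    system: MolecularSystem,
    max_memory_mb: float = 2000.0,
) -> TwoParticleTensors:
    """Conventional 4-index Coulomb tensors at the current geometry.

    ``ep`` is a bare Coulomb coupling — the species are distinguishable, so
    no cross exchange exists.  ``pp`` is built only when two or more quantum
    protons are present.
    """
    basis_e.validate_against(system)
    ne = basis_e.n_functions
    np_ = basis_p.n_functions if basis_p is not None else 0
    need_pp = basis_p is not None and system.n_quantum >= 2 and np_ > 0
    est = ne**4 + np_**4 * (1 if need_pp else 0) + (ne * np_) ** 2
    # cartesian work arrays are what actually dominates
    est_mb = est * 8 * 2.5 / 1e6
    if est_mb > max_memory_mb:
        raise MemoryError(
            f"two-particle tensors would need ~{est_mb:.0f} MB "
            f"(cap {max_memory_mb:.0f} MB); use a smaller basis or an "
            "integral-direct strategy"
        )
    out = TwoParticleTensors()
    fbe = _FlatBasis(basis_e, system) if ne else None
    if ne:
        out.ee = _eri(fbe, fbe, True)
    if basis_p is not None and np_:
        basis_p.validate_against(system)
        fbp = _FlatBasis(basis_p, system)
        if need_pp:
            out.pp = _eri(fbp, fbp, True)
        if ne:
            out.ep = _eri(fbe, fbp, False)
    return out


def overlap_pair(alpha: float, beta: float, R: float) -> float:
    """Overlap of two normalized s Gaussians a distance R apart (closed form)."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("exponents must be positive")
    p = alpha + beta
    return (2.0 * math.sqrt(alpha * beta) / p) ** 1.5 * math.exp(
        -alpha * beta * R * R / p
    )
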