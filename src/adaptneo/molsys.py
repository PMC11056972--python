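"""Molecular systems with a classical/quantum center partition.

A nuclear-electronic orbital (NEO) calculation splits the nuclei into
classical point charges at positions ``r_c`` and quantum centers ``r_q``.
A quantum center is *not* a point charge in the Hamiltonian: it only
anchors basis functions (protonic, and the electronic functions that
belong to that atom), while the proton itself is described by a density.
Moving ``r_q`` therefore changes the basis, not the Hamiltonian's
point-charge field.

Coordinates are stored in Bohr; XYZ files are read and written in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

__all__ = [
    "AtomicCenter",
    "MolecularSystem",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "transform",
]

_ELEMENTS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr"
).split()
_Z_OF = {sym: i + 1 for i, sym in enumerate(_ELEMENTS)}


class XYZParseError(ValueError):
    """Malformed XYZ input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class AtomicCenter:
    """One nuclear center: a classical point charge or a quantum placeholder."""

    element: str
    position: np.ndarray  # (3,) Bohr
    nuclear_charge: int
    is_quantum: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.nuclear_charge < 1:
            raise ValueError("nuclear_charge must be >= 1")
        if self.is_quantum and self.nuclear_charge != 1:
            raise ValueError(
                "quantum centers must be hydrogen (nuclear charge 1)"
            )


@dataclass(frozen=True)
class MolecularSystem:
    """An ordered set of centers plus the total molecular charge."""

    centers: tuple[AtomicCenter, ...]
    total_charge: int = 0

    def __post_init__(self):
        object.__setattr__(self, "centers", tuple(self.centers))
        if self.n_electrons < 0:
            raise ValueError("negative electron count")
        if self.n_electrons % 2 == 1 and self.n_electrons != 1:
            raise ValueError(
                f"odd electron count {self.n_electrons}: the restricted "
                "electronic treatment supports even counts (or exactly one "
                "electron)"
            )

    @property
    def n_quantum(self) -> int:
        return sum(c.is_quantum for c in self.centers)

    @property
    def n_electrons(self) -> int:
        """Electrons are counted against *all* nuclei, quantum ones included."""
        return sum(c.nuclear_charge for c in self.centers) - self.total_charge

    @property
    def quantum_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.centers) if c.is_quantum)

    @property
    def classical_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.centers) if not c.is_quantum)

    def positions(self) -> np.ndarray:
        """All center positions, (n, 3) Bohr."""
        return np.array([c.position for c in self.centers], dtype=float)

    def point_charges(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions and charges of the *classical* nuclei only.

        Quantum centers never appear here: their charge enters through the
        protonic density.
        """
        idx = self.classical_indices
        if not idx:
            return np.zeros((0, 3)), np.zeros((0,))
        pos = np.array([self.centers[i].position for i in idx])
        chg = np.array([float(self.centers[i].nuclear_charge) for i in idx])
        return pos, chg

    def classical_repulsion(self) -> float:
        """Coulomb energy of the classical point charges, hartree."""
        pos, chg = self.point_charges()
        e = 0.0
        for a in range(len(chg)):
            for b in range(a + 1, len(chg)):
                e += chg[a] * chg[b] / np.linalg.norm(pos[a] - pos[b])
        return e

    def with_positions(self, positions: np.ndarray) -> "MolecularSystem":
        """Same system with all center positions replaced (Bohr)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.centers), 3):
            raise ValueError("positions shape mismatch")
        new = tuple(
            replace(c, position=positions[i].copy())
            for i, c in enumerate(self.centers)
        )
        return MolecularSystem(new, self.total_charge)

    def move_center(self, index: int, position: np.ndarray) -> "MolecularSystem":
        pos = self.positions()
        pos[index] = position
        return self.with_positions(pos)


def read_xyz(
    path,
    quantum_selector: list[int] | tuple[int, ...] = (),
    total_charge: int = 0,
) -> MolecularSystem:
    """Read an XYZ file (Angstrom) and flag quantum hydrogens.

    ``quantum_selector`` holds 1-based atom indices; each must refer to a
    hydrogen.  Positions are converted to Bohr.
    """
    with open(path) as fh:
        lines = fh.readlines()
    return _parse_xyz_lines(lines, quantum_selector, total_charge)


def _parse_xyz_lines(lines, quantum_selector, total_charge):
    if not lines:
        raise XYZParseError("empty file", line=1)
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError("expected an atom count", line=1) from None
    if len(lines) < natoms + 2:
        raise XYZParseError(
            f"expected {natoms} atom lines, file has {len(lines) - 2}",
            line=len(lines),
        )
    selector = set(quantum_selector)
    for i in selector:
        if not (1 <= i <= natoms):
            raise ValueError(f"quantum selector index {i} out of range 1..{natoms}")
    centers = []
    for i in range(natoms):
        lineno = i + 3
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise XYZParseError("expected 'element x y z'", line=lineno)
        sym = parts[0].capitalize()
        if sym not in _Z_OF:
            raise XYZParseError(f"unknown element {parts[0]!r}", line=lineno)
        try:
            xyz = np.array([float(p) for p in parts[1:4]])
        except ValueError:
            raise XYZParseError("non-numeric coordinate", line=lineno) from None
        is_q = (i + 1) in selector
        if is_q and sym != "H":
            raise ValueError(
                f"quantum selector index {i + 1} refers to {sym}; only H atoms "
                "may be quantum"
            )
        centers.append(
            AtomicCenter(sym, xyz * BOHR_PER_ANGSTROM, _Z_OF[sym], is_q)
        )
    return MolecularSystem(tuple(centers), total_charge)


def write_xyz(system: MolecularSystem, path, comment: str = "") -> None:
    """Write the system as XYZ in Angstrom (quantum flags noted in comment)."""
    qidx = [str(i + 1) for i in system.quantum_indices]
    if qidx and not comment:
        comment = "quantum atoms (1-based): " + " ".join(qidx)
    with open(path, "w") as fh:
        fh.write(f"{len(system.centers)}\n{comment}\n")
        for c in system.centers:
            x, y, z = c.position * ANGSTROM_PER_BOHR
            fh.write(f"{c.element:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def transform(
    system: MolecularSystem,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> MolecularSystem:
    """Apply the rigid motion ``r -> R r + t`` to every center."""
    rot = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float).reshape(3)
    if rot.shape != (3, 3) or np.abs(rot @ rot.T - np.eye(3)).max() > 1e-10:
        raise ValueError("rotation must be orthogonal (within 1e-10)")
    return system.with_positions(system.positions() @ rot.T + t)
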