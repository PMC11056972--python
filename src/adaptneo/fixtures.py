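"""Built-in model systems, each runnable end-to-end in seconds.

These bundled fixtures stand in for download-only production structures:
tiny one-quantum-proton systems whose symmetry or single-well character is
known by construction, with recommended compact bases.

* ``h_atom``       — one quantum proton + one electron, no classical nuclei;
                     the exact nonrelativistic limit is -mu/2 hartree, a
                     strict lower bound for the mean-field product ansatz.
* ``h2_1q``        — H2 at the standard 1.4 Bohr separation with one of the
                     protons quantum.
* ``hehhe_cation`` — linear, symmetric [He-H-He]+ with the central proton
                     quantum; the midpoint is a symmetry fixed point of the
                     adaptive update.
* ``hbond_toy``    — linear F-H...He: an asymmetric single-well
                     donor-H-acceptor system for minimum-shift tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from .basis import BasisSet, load_basis
from .molsys import AtomicCenter, MolecularSystem

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class Fixture:
    name: str
    system: MolecularSystem
    electron_basis: str
    proton_basis: str
    description: str
    symmetric_axis: tuple | None = None  # unit axis of a known symmetry, if any

    def bases(self) -> tuple[BasisSet, BasisSet | None]:
        be = load_basis(self.electron_basis, "electron", self.system)
        bp = (
            load_basis(self.proton_basis, "proton", self.system)
            if self.system.n_quantum
            else None
        )
        return be, bp


def _h_atom() -> Fixture:
    sys_ = MolecularSystem(
        (AtomicCenter("H", (0.0, 0.0, 0.0), 1, is_quantum=True),), 0
    )
    return Fixture(
        "h_atom", sys_,
        electron_basis="et-10s(0.02,200)",
        proton_basis="et-8s",
        description="fully quantum hydrogen atom (1 electron, 1 quantum proton)",
    )


def _h2_1q() -> Fixture:
    sys_ = MolecularSystem(
        (
            AtomicCenter("H", (0.0, 0.0, 0.0), 1),
            AtomicCenter("H", (0.0, 0.0, 1.4), 1, is_quantum=True),
        ),
        0,
    )
    return Fixture(
        "h2_1q", sys_,
        electron_basis="sto-3g",
        proton_basis="et-6s3p",
        description="H2 (R = 1.4 Bohr) with one quantum proton",
        symmetric_axis=(0.0, 0.0, 1.0),
    )


def _hehhe_cation() -> Fixture:
    sys_ = MolecularSystem(
        (
            AtomicCenter("He", (0.0, 0.0, -2.0), 2),
            AtomicCenter("H", (0.0, 0.0, 0.0), 1, is_quantum=True),
            AtomicCenter("He", (0.0, 0.0, 2.0), 2),
        ),
        +1,
    )
    return Fixture(
        "hehhe_cation", sys_,
        electron_basis="sto-3g",
        proton_basis="et-6s3p",
        description="linear symmetric [He-H-He]+ with the proton quantum",
        symmetric_axis=(0.0, 0.0, 1.0),
    )


def _hbond_toy() -> Fixture:
    # compressed donor-acceptor contact: the proton well is single,
    # asymmetric and comparatively soft (the low-barrier hydrogen-bond
    # regime where nuclear quantum effects are largest)
    sys_ = MolecularSystem(
        (
            AtomicCenter("F", (0.0, 0.0, 0.0), 9),
            AtomicCenter("H", (0.0, 0.0, 1.85), 1, is_quantum=True),
            AtomicCenter("He", (0.0, 0.0, 3.8), 2),
        ),
        0,
    )
    return Fixture(
        "hbond_toy", sys_,
        electron_basis="sto-3g-aug",
        proton_basis="et-4s2p",
        description=(
            "compressed linear F-H...He donor-H-acceptor toy with an "
            "asymmetric single-well proton potential"
        ),
        symmetric_axis=(0.0, 0.0, 1.0),
    )


_REGISTRY = {
    "h_atom": _h_atom,
    "h2_1q": _h2_1q,
    "hehhe_cation": _hehhe_cation,
    "hbond_toy": _hbond_toy,
}

FIXTURE_NAMES = tuple(sorted(_REGISTRY))


def make_fixture(name: str) -> Fixture:
    """Deterministically construct a bundled fixture by name."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
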