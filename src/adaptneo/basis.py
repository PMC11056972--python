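"""Contracted Gaussian basis sets for electrons and quantum protons.

Shells are attached to *centers* of a :class:`~adaptneo.molsys.MolecularSystem`
by index, so moving a center (the adaptive update) automatically moves every
function that lives on it — protonic and electronic alike.

Two sources are supported: the common text block format of basis-set
repositories (element header, shell-type letter, exponent/coefficient rows)
and even-tempered generation ``alpha0 * beta**k``.  Solid-harmonic
(spherical) functions are used for l >= 2.
"""

from __future__ import annotations

import json
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .integrals.spherical import cart_components, transform_matrix
from .molsys import MolecularSystem
from .units import PROTON_MASS

__all__ = [
    "GaussianShell",
    "BasisSet",
    "BasisParseError",
    "load_basis",
    "even_tempered",
    "parse_basis_text",
]

log = logging.getLogger(__name__)

_L_OF_LETTER = {"S": 0, "P": 1, "D": 2, "F": 3, "G": 4}
_LETTER_OF_L = {v: k for k, v in _L_OF_LETTER.items()}


class BasisParseError(ValueError):
    pass


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def _mono_overlap_1d(i: int, j: int, p: float) -> float:
    """Integral of x^(i+j) exp(-p x^2) over the real line."""
    n = i + j
    if n % 2 == 1:
        return 0.0
    return _double_factorial(n - 1) / (2.0 * p) ** (n // 2) * math.sqrt(
        math.pi / p
    )


@dataclass(frozen=True)
class GaussianShell:
    """One contracted shell: shared exponents, one angular momentum.

    ``coefficients`` refer to normalized spherical primitives (the usual
    published convention); the normalized weights over raw Cartesian
    monomials are exposed via :meth:`weights`.
    """

    center_index: int
    angular_momentum: int
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]

    def __post_init__(self):
        exps = tuple(float(e) for e in self.exponents)
        coefs = tuple(float(c) for c in self.coefficients)
        if len(exps) != len(coefs) or not exps:
            raise ValueError("exponents and coefficients must match and be non-empty")
        if any(e <= 0 for e in exps):
            raise ValueError("exponents must be strictly positive")
        if self.angular_momentum < 0 or self.angular_momentum > 4:
            raise ValueError("angular momentum must be in 0..4")
        order = np.argsort(exps)[::-1]
        object.__setattr__(self, "exponents", tuple(exps[i] for i in order))
        object.__setattr__(self, "coefficients", tuple(coefs[i] for i in order))

    @property
    def n_sph(self) -> int:
        return 2 * self.angular_momentum + 1

    def weights(self) -> np.ndarray:
        """Primitive weights over raw Cartesian monomials, scaled so the
        contracted solid-harmonic function has unit self-overlap."""
        l = self.angular_momentum
        a = np.array(self.exponents)
        w = np.array(self.coefficients) * a ** ((2 * l + 3) / 4.0)
        # exact self-overlap of the m = -l spherical component
        T = transform_matrix(l)[:, 0]
        comps = cart_components(l)
        s = 0.0
        for ia, wa in enumerate(w):
            for ib, wb in enumerate(w):
                p = a[ia] + a[ib]
                acc = 0.0
                for c1, t1 in zip(comps, T):
                    if t1 == 0.0:
                        continue
                    for c2, t2 in zip(comps, T):
                        if t2 == 0.0:
                            continue
                        acc += (
                            t1
                            * t2
                            * _mono_overlap_1d(c1[0], c2[0], p)
                            * _mono_overlap_1d(c1[1], c2[1], p)
                            * _mono_overlap_1d(c1[2], c2[2], p)
                        )
                s += wa * wb * acc
        return w / math.sqrt(s)


@dataclass(frozen=True)
class BasisSet:
    """All shells of one particle species, attached to system centers."""

    species: str  # "electron" | "proton"
    shells: tuple[GaussianShell, ...]
    particle_mass: float = 1.0

    def __post_init__(self):
        if self.species not in ("electron", "proton"):
            raise ValueError("species must be 'electron' or 'proton'")
        if self.species == "electron" and self.particle_mass != 1.0:
            raise ValueError("electrons have unit mass")
        if self.species == "proton" and abs(
            self.particle_mass - PROTON_MASS
        ) > 1e-6:
            raise ValueError("proton mass must be 1836.15267343 m_e")
        object.__setattr__(self, "shells", tuple(self.shells))

    @property
    def n_functions(self) -> int:
        return sum(sh.n_sph for sh in self.shells)

    def validate_against(self, system: MolecularSystem) -> None:
        n = len(system.centers)
        for sh in self.shells:
            if not (0 <= sh.center_index < n):
                raise ValueError(f"shell center {sh.center_index} out of range")
            if self.species == "proton" and not system.centers[
                sh.center_index
            ].is_quantum:
                raise ValueError(
                    "protonic shells may only sit on quantum centers"
                )


# ---------------------------------------------------------------------------
# parsing

def parse_basis_text(text: str) -> dict[str, list[tuple[int, list, list]]]:
    """Parse the repository block format into {element: [(l, exps, coefs)]}.

    SP blocks are split into an S and a P shell sharing exponents.
    """
    out: dict[str, list] = {}
    lines = [ln.split("!")[0].rstrip() for ln in text.splitlines()]
    i = 0
    n = len(lines)
    while i < n:
        ln = lines[i].strip()
        if not ln or ln.startswith("****"):
            i += 1
            continue
        parts = ln.split()
        if not re.fullmatch(r"[A-Za-z]{1,2}", parts[0]):
            raise BasisParseError(f"line {i + 1}: expected an element header, got {ln!r}")
        element = parts[0].capitalize()
        out.setdefault(element, [])
        i += 1
        while i < n:
            ln = lines[i].strip()
            if not ln:
                i += 1
                continue
            if ln.startswith("****"):
                i += 1
                break
            hdr = ln.split()
            letter = hdr[0].upper()
            if letter not in _L_OF_LETTER and letter != "SP":
                raise BasisParseError(
                    f"line {i + 1}: unknown shell type {hdr[0]!r}"
                )
            try:
                nprim = int(hdr[1])
            except (IndexError, ValueError):
                raise BasisParseError(
                    f"line {i + 1}: shell header needs a primitive count"
                ) from None
            rows = []
            for k in range(nprim):
                i += 1
                if i >= n:
                    raise BasisParseError(f"line {i + 1}: truncated shell block")
                row = lines[i].replace("D", "E").replace("d", "e").split()
                try:
                    rows.append([float(x) for x in row])
                except ValueError:
                    raise BasisParseError(
                        f"line {i + 1}: non-numeric primitive row"
                    ) from None
            i += 1
            exps = [r[0] for r in rows]
            if letter == "SP":
                if any(len(r) < 3 for r in rows):
                    raise BasisParseError("SP block needs two coefficient columns")
                out[element].append((0, exps, [r[1] for r in rows]))
                out[element].append((1, exps, [r[2] for r in rows]))
            else:
                if any(len(r) < 2 for r in rows):
                    raise BasisParseError("shell row needs exponent + coefficient")
                out[element].append(
                    (_L_OF_LETTER[letter], exps, [r[1] for r in rows])
                )
    return out


def _parse_basis_json(text: str):
    data = json.loads(text)
    out = {}
    for element, shells in data.items():
        out[element.capitalize()] = [
            (
                sh["l"] if isinstance(sh["l"], int) else _L_OF_LETTER[sh["l"].upper()],
                list(sh["exponents"]),
                list(sh["coefficients"]),
            )
            for sh in shells
        ]
    return out


_ET_NAME = re.compile(
    r"et-((?:\d+[spdfg])+)(?:\((?P<lo>[\d.eE+-]+),(?P<hi>[\d.eE+-]+)\))?"
)


def _even_tempered_from_name(name: str):
    """Shell recipe from a name like ``et-8s8p8d`` or ``et-6s6p(2,64)``.

    Without an explicit range, exponents span 2..64 (the documented protonic
    fallback window).
    """
    m = _ET_NAME.fullmatch(name)
    if m is None:
        return None
    lo = float(m.group("lo")) if m.group("lo") else 2.0
    hi = float(m.group("hi")) if m.group("hi") else 64.0
    blocks = re.findall(r"(\d+)([spdfg])", m.group(1))
    recipe = []
    for cnt, letter in blocks:
        cnt = int(cnt)
        beta = (hi / lo) ** (1.0 / (cnt - 1)) if cnt > 1 else 2.0
        recipe.append((_L_OF_LETTER[letter.upper()], cnt, lo, beta))
    return recipe


def even_tempered(
    center_index: int,
    l_max: int,
    n_per_l: int,
    alpha0: float,
    beta: float,
) -> list[GaussianShell]:
    """Uncontracted even-tempered shells alpha0*beta**k, k = 0..n-1,
    replicated for every l <= l_max."""
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    if beta <= 1:
        raise ValueError("beta must exceed 1")
    if n_per_l < 1:
        raise ValueError("n_per_l must be >= 1")
    shells = []
    for l in range(l_max + 1):
        for k in range(n_per_l):
            shells.append(
                GaussianShell(center_index, l, (alpha0 * beta**k,), (1.0,))
            )
    return shells


def _builtin_source(name: str) -> str | None:
    fname = name.lower().replace("*", "_st") + ".bas"
    ref = resources.files("adaptneo") / "data" / fname
    try:
        return ref.read_text()
    except FileNotFoundError:
        return None


def load_basis(source, species: str, system: MolecularSystem) -> BasisSet:
    """Instantiate a basis for ``species`` on every eligible center.

    ``source`` may be a file path, a bundled basis name (e.g. ``sto-3g``),
    or an even-tempered recipe name like ``et-8s8p8d`` / ``et-6s6p(2,64)``.
    Electronic shells go on *all* centers (quantum ones included — those
    functions ride along with the adaptive update); protonic shells go on
    quantum centers only.
    """
    mass = 1.0 if species == "electron" else PROTON_MASS
    if species == "electron":
        targets = list(range(len(system.centers)))
    else:
        targets = list(system.quantum_indices)
        if not targets:
            warnings.warn(
                "proton basis requested for a system without quantum centers; "
                "returning an empty basis",
                stacklevel=2,
            )
            return BasisSet(species, (), mass)

    recipe = _even_tempered_from_name(str(source)) if isinstance(source, str) else None
    if recipe is not None:
        shells = []
        for idx in targets:
            for l, cnt, a0, beta in recipe:
                shells.extend(even_tempered(idx, l, cnt, a0, beta))
        bs = BasisSet(species, tuple(shells), mass)
        bs.validate_against(system)
        return bs

    text = None
    if isinstance(source, (str, Path)) and Path(str(source)).is_file():
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = _builtin_source(source)
        if text is None:
            raise BasisParseError(
                f"unknown basis {source!r}: not a file, bundled set, or "
                "even-tempered recipe"
            )
    else:
        raise TypeError("source must be a path or name")

    if text.lstrip().startswith("{"):
        table = _parse_basis_json(text)
    else:
        table = parse_basis_text(text)

    shells = []
    for idx in targets:
        element = system.centers[idx].element
        key = "H" if species == "proton" else element
        if key not in table:
            raise BasisParseError(
                f"element {key} not found in basis source {source!r}"
            )
        for l, exps, coefs in table[key]:
            shells.append(GaussianShell(idx, l, tuple(exps), tuple(coefs)))
    bs = BasisSet(species, tuple(shells), mass)
    bs.validate_against(system)
    return bs
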