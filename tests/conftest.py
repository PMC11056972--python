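"""Shared fixtures: small systems and (cached) converged reference runs.

Heavy SCF results are session-scoped so that independent tests can assert
different properties of one converged calculation without re-running it.
"""

from __future__ import annotations

import numpy as np
import pytest

from adaptneo.adaptive import run_adaptive_neo
from adaptneo.basis import BasisSet, GaussianShell, load_basis
from adaptneo.fixtures import make_fixture
from adaptneo.molsys import AtomicCenter, MolecularSystem
from adaptneo.optimize import optimize_rq
from adaptneo.scf import run_neo_scf


@pytest.fixture(scope="session")
def water_system():
    # a standard bent water geometry (Bohr)
    return MolecularSystem(
        (
            AtomicCenter("O", (0.0, 0.0, -0.143225816552), 8),
            AtomicCenter("H", (0.0, 1.638036840407, 1.136548822547), 1),
            AtomicCenter("H", (0.0, -1.638036840407, 1.136548822547), 1),
        ),
        0,
    )


@pytest.fixture(scope="session")
def water_rhf(water_system):
    basis = load_basis("sto-3g", "electron", water_system)
    state, _, ints = run_neo_scf(water_system, basis)
    return water_system, basis, state, ints


@pytest.fixture(scope="session")
def h_atom_neo():
    fx = make_fixture("h_atom")
    be, bp = fx.bases()
    state, _, ints = run_neo_scf(fx.system, be, bp)
    return fx, be, bp, state, ints


@pytest.fixture(scope="session")
def hehhe():
    fx = make_fixture("hehhe_cation")
    be, bp = fx.bases()
    return fx, be, bp


@pytest.fixture(scope="session")
def hehhe_adaptive(hehhe):
    fx, be, bp = hehhe
    state, final_system, trace = run_adaptive_neo(fx.system, be, bp)
    return state, final_system, trace


@pytest.fixture(scope="session")
def hbond():
    fx = make_fixture("hbond_toy")
    be, bp = fx.bases()
    return fx, be, bp


@pytest.fixture(scope="session")
def hbond_adaptive(hbond):
    fx, be, bp = hbond
    state, final_system, trace = run_adaptive_neo(fx.system, be, bp)
    return state, final_system, trace


@pytest.fixture(scope="session")
def hbond_optimized(hbond):
    fx, be, bp = hbond
    return optimize_rq(fx.system, be, bp)


@pytest.fixture()
def single_s_electron_system():
    sys_ = MolecularSystem(
        (AtomicCenter("H", (0.0, 0.0, 0.0), 1),), total_charge=1
    )
    basis = BasisSet(
        "electron", (GaussianShell(0, 0, (1.0,), (1.0,)),)
    )
    return sys_, basis
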