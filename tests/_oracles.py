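"""Independent SCF-level oracle: direct energy-functional minimization."""

import numpy as np
import scipy.linalg
import scipy.optimize


def rhf_energy_by_direct_minimization(ints, n_occ, e_nuc):
    """Independent oracle: minimize the closed-shell energy functional over
    orthonormal orbitals parametrized by an orbital rotation, never touching
    the package's Roothaan/DIIS machinery."""
    h = ints.electron.core
    S = ints.electron.overlap
    ee = ints.tensors.ee
    n = h.shape[0]
    # scipy generalized eigensolver supplies the starting orbitals
    _, C0 = scipy.linalg.eigh(h, S)
    iu = np.triu_indices(n, k=1)

    def energy(params):
        X = np.zeros((n, n))
        X[iu] = params
        X -= X.T
        C = C0 @ scipy.linalg.expm(X)
        D = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        J = np.einsum("pqrs,rs->pq", ee, D)
        K = np.einsum("prqs,rs->pq", ee, D)
        return float(np.einsum("pq,pq->", D, h + 0.5 * (J - 0.5 * K))) + e_nuc

    res = scipy.optimize.minimize(
        energy, np.zeros(len(iu[0])), method="BFGS",
        options={"gtol": 1e-10, "maxiter": 2000},
    )
    return res.fun
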