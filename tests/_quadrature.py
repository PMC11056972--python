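"""Independent numerical-quadrature oracles for Gaussian integrals.

Deliberately shares no code with the package's McMurchie-Davidson engine:
polynomial-times-Gaussian factors are integrated with Gauss-Hermite rules
(exact for polynomials), and every Coulomb kernel is handled through the
resolvent identity 1/r = (2/sqrt(pi)) * Int_0^inf exp(-t^2 r^2) dt with an
adaptive 1-D outer quadrature.  Primitives are *unnormalized* Cartesian
monomial Gaussians (x-Ax)^i (y-Ay)^j (z-Az)^k exp(-a |r-A|^2).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.integrate import quad

_NODES, _WEIGHTS = hermgauss(24)


def _poly1d(x, c, n):
    """(x - c)**n evaluated elementwise."""
    return (x - c) ** n


def _gh_1d(func, p, center):
    """Integral of func(x) * exp(-p (x - center)^2) dx, func polynomial."""
    x = center + _NODES / np.sqrt(p)
    return float(np.sum(_WEIGHTS * func(x)) / np.sqrt(p))


def _gauss_product(a, A, b, B):
    p = a + b
    P = (a * np.asarray(A, float) + b * np.asarray(B, float)) / p
    pref = np.exp(-a * b / p * np.sum((np.asarray(A) - np.asarray(B)) ** 2))
    return p, P, pref


def overlap_prim(la, A, a, lb, B, b):
    """<a|b> for monomial primitives; la/lb are (i, j, k) tuples."""
    p, P, pref = _gauss_product(a, A, b, B)
    out = pref
    for d in range(3):
        out *= _gh_1d(
            lambda x: _poly1d(x, A[d], la[d]) * _poly1d(x, B[d], lb[d]),
            p, P[d],
        )
    return out


def _dpoly(x, c, n, expnt):
    """d/dx [ (x-c)^n e^{-expnt (x-c)^2} ] divided by the Gaussian factor."""
    t = x - c
    out = -2.0 * expnt * t ** (n + 1)
    if n > 0:
        out = out + n * t ** (n - 1)
    return out


def kinetic_prim(la, A, a, lb, B, b, mass=1.0):
    """<a| -laplacian/(2 mass) |b> via integration by parts."""
    p, P, pref = _gauss_product(a, A, b, B)
    total = 0.0
    for d in range(3):
        term = pref
        for e in range(3):
            if e == d:
                term *= _gh_1d(
                    lambda x: _dpoly(x, A[e], la[e], a)
                    * _dpoly(x, B[e], lb[e], b),
                    p, P[e],
                )
            else:
                term *= _gh_1d(
                    lambda x: _poly1d(x, A[e], la[e]) * _poly1d(x, B[e], lb[e]),
                    p, P[e],
                )
        total += term
    return 0.5 * total / mass


def moment_prim(la, A, a, lb, B, b, axis):
    """<a| r_axis |b> (moment about the origin)."""
    p, P, pref = _gauss_product(a, A, b, B)
    out = pref
    for d in range(3):
        if d == axis:
            out *= _gh_1d(
                lambda x: x * _poly1d(x, A[d], la[d]) * _poly1d(x, B[d], lb[d]),
                p, P[d],
            )
        else:
            out *= _gh_1d(
                lambda x: _poly1d(x, A[d], la[d]) * _poly1d(x, B[d], lb[d]),
                p, P[d],
            )
    return out


def attraction_prim(la, A, a, lb, B, b, C):
    """<a| 1/|r-C| |b> via the Gaussian resolvent of the Coulomb kernel."""
    C = np.asarray(C, float)

    def integrand(u):
        t = u / (1.0 - u)
        t2 = t * t
        val = 1.0
        for d in range(3):
            # three Gaussian factors: a@A, b@B, t2@C
            p = a + b + t2
            ctr = (a * A[d] + b * B[d] + t2 * C[d]) / p
            # complete the square: residual constant
            q = (
                a * A[d] ** 2 + b * B[d] ** 2 + t2 * C[d] ** 2
                - p * ctr ** 2
            )
            val *= np.exp(-q) * _gh_1d(
                lambda x: _poly1d(x, A[d], la[d]) * _poly1d(x, B[d], lb[d]),
                p, ctr,
            )
        return val / (1.0 - u) ** 2

    out, _ = quad(integrand, 0.0, 1.0, epsabs=1e-13, epsrel=1e-12, limit=200)
    return 2.0 / np.sqrt(np.pi) * out


def eri_prim(la, A, a, lb, B, b, lc, C, c, ld, D, d):
    """(ab|cd) for monomial primitives via the resolvent + 2-D Gauss-Hermite."""
    A, B, C, D = (np.asarray(v, float) for v in (A, B, C, D))
    p, P, prefab = _gauss_product(a, A, b, B)
    q, Q, prefcd = _gauss_product(c, C, d, D)

    def integrand(u):
        t = u / (1.0 - u)
        t2 = t * t
        val = prefab * prefcd
        for dim in range(3):
            # exponent: p(x1-P)^2 + q(x2-Q)^2 + t2 (x1-x2)^2
            M = np.array([[p + t2, -t2], [-t2, q + t2]])
            rhs = np.array([p * P[dim], q * Q[dim]])
            x0 = np.linalg.solve(M, rhs)
            const = p * P[dim] ** 2 + q * Q[dim] ** 2 - x0 @ M @ x0
            lam, V = np.linalg.eigh(M)
            acc = 0.0
            for i1, (y1, w1) in enumerate(zip(_NODES, _WEIGHTS)):
                ys = V[:, 0] * y1 / np.sqrt(lam[0])
                for y2, w2 in zip(_NODES, _WEIGHTS):
                    x = x0 + ys + V[:, 1] * y2 / np.sqrt(lam[1])
                    f = (
                        _poly1d(x[0], A[dim], la[dim])
                        * _poly1d(x[0], B[dim], lb[dim])
                        * _poly1d(x[1], C[dim], lc[dim])
                        * _poly1d(x[1], D[dim], ld[dim])
                    )
                    acc += w1 * w2 * f
            val *= acc / np.sqrt(lam[0] * lam[1]) * np.exp(-const)
        return val / (1.0 - u) ** 2

    out, _ = quad(integrand, 0.0, 1.0, epsabs=1e-12, epsrel=1e-11, limit=200)
    return 2.0 / np.sqrt(np.pi) * out
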