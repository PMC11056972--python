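"""Real solid harmonics and the Cartesian-to-spherical shell transform.

Integrals are evaluated over raw Cartesian monomial Gaussians
``x^i y^j z^k exp(-a r^2)`` and transformed to the solid-harmonic
(spherical) AO basis used by correlation-consistent sets.  The real solid
harmonics S_lm are built by the standard two-term recursion

    S_00 = 1
    S_{l+1,l+1}  = sqrt(2^{d_l0} (2l+1)/(2l+2)) (x S_ll - y S_{l,-l})
    S_{l+1,-l-1} = sqrt(2^{d_l0} (2l+1)/(2l+2)) (y S_ll + x S_{l,-l})
    S_{l+1,m}    = ((2l+1) z S_lm - sqrt((l+m)(l-m)) r^2 S_{l-1,m})
                   / sqrt((l+1+m)(l+1-m))

(Schmidt semi-normalized, so every m of a shell carries the same radial
norm and one normalization constant per contracted shell suffices).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["n_cart", "cart_components", "solid_harmonic_poly", "transform_matrix"]


def n_cart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


@lru_cache(maxsize=None)
def cart_components(l: int) -> tuple[tuple[int, int, int], ...]:
    """Cartesian monomial exponents of shell l, ordered lexicographically
    by descending (lx, ly)."""
    return tuple(
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    )


@lru_cache(maxsize=None)
def _solid_harmonics_up_to(l: int):
    """All S_{k,m} for k <= l as {(lx,ly,lz): coeff} dicts, keyed (k, m)."""
    polys = {(0, 0): {(0, 0, 0): 1.0}}

    def _mul(poly, dx, dy, dz, scale=1.0):
        return {
            (a + dx, b + dy, c + dz): v * scale for (a, b, c), v in poly.items()
        }

    def _add(*polys_):
        out = {}
        for p in polys_:
            for k, v in p.items():
                out[k] = out.get(k, 0.0) + v
        return {k: v for k, v in out.items() if abs(v) > 1e-15}

    for k in range(l):
        top = polys[(k, k)]
        bot = polys[(k, -k)] if k > 0 else {}
        f = np.sqrt((2.0 if k == 0 else 1.0) * (2 * k + 1) / (2 * k + 2))
        polys[(k + 1, k + 1)] = _add(
            _mul(top, 1, 0, 0, f), _mul(bot, 0, 1, 0, -f)
        )
        polys[(k + 1, -(k + 1))] = _add(
            _mul(top, 0, 1, 0, f), _mul(bot, 1, 0, 0, f)
        )
        for m in range(-k, k + 1):
            num = _mul(polys[(k, m)], 0, 0, 1, 2 * k + 1)
            if abs(m) <= k - 1:
                prev = polys[(k - 1, m)]
                c = -np.sqrt(float((k + m) * (k - m)))
                num = _add(
                    num,
                    _mul(prev, 2, 0, 0, c),
                    _mul(prev, 0, 2, 0, c),
                    _mul(prev, 0, 0, 2, c),
                )
            polys[(k + 1, m)] = {
                key: v / np.sqrt(float((k + 1 + m) * (k + 1 - m)))
                for key, v in num.items()
            }
    return polys


def solid_harmonic_poly(l: int, m: int) -> dict[tuple[int, int, int], float]:
    """S_lm as a {(lx, ly, lz): coefficient} monomial dict."""
    return dict(_solid_harmonics_up_to(max(l, 0))[(l, m)])


@lru_cache(maxsize=None)
def transform_matrix(l: int) -> np.ndarray:
    """(n_cart(l), 2l+1) matrix T with AO_m = sum_cart T[cart, m] cart.

    Spherical order: m = -l, ..., 0, ..., +l.
    """
    comps = cart_components(l)
    idx = {c: i for i, c in enumerate(comps)}
    T = np.zeros((n_cart(l), 2 * l + 1))
    for col, m in enumerate(range(-l, l + 1)):
        for key, v in solid_harmonic_poly(l, m).items():
            T[idx[key], col] = v
    return T
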