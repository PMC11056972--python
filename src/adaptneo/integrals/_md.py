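"""McMurchie-Davidson evaluation of Gaussian integrals (numba kernels).

Everything here works on *flattened* shell arrays over raw Cartesian
monomial primitives ``x^i y^j z^k exp(-a r^2)``; primitive normalization
and contraction live in the weights, the spherical transform is applied
by the engine afterwards.  Supported angular momenta: l <= LMAX = 4.

Conventions
-----------
* Hermite expansion coefficients E_t^{ij} follow Helgaker-Taylor; the
  pre-exponential K_AB = exp(-mu X_AB^2) is folded into E_0^{00}.
* The point-charge and Coulomb kernels are *positive*; attraction or
  repulsion signs are applied by the caller.
* ``boys_fill`` switches between the downward series (x < 30) and the
  upward recursion seeded by the asymptotic F_0 (x >= 30), accurate to
  ~1e-14 across the switch.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LMAX = 4
# E-table dims for one-particle work (kinetic needs ket l + 2)
_NE1 = LMAX + 1
_NE2 = LMAX + 3
_NET = 2 * LMAX + 3


@njit(cache=True)
def boys_fill(mmax, x, out):
    if x < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if x < 30.0:
        # series at mmax, then downward recursion
        s = 1.0 / (2.0 * mmax + 1.0)
        term = s
        k = 1
        while k < 300:
            term *= 2.0 * x / (2.0 * mmax + 2.0 * k + 1.0)
            s += term
            if term < 1e-17 * s:
                break
            k += 1
        ex = math.exp(-x)
        out[mmax] = s * ex
        for m in range(mmax - 1, -1, -1):
            out[m] = (2.0 * x * out[m + 1] + ex) / (2.0 * m + 1.0)
    else:
        ex = math.exp(-x)
        out[0] = 0.5 * math.sqrt(math.pi / x) * math.erf(math.sqrt(x))
        for m in range(mmax):
            out[m + 1] = ((2.0 * m + 1.0) * out[m] - ex) / (2.0 * x)


@njit(cache=True)
def e_table(la, lb, a, b, ab, out):
    """Fill Hermite coefficients E_t^{ij} for one Cartesian dimension.

    out[i, j, t]; ab = A - B along this dimension.  K_AB included in E_0^00.
    """
    p = a + b
    mu = a * b / p
    pa = -b * ab / p  # P - A
    pb = a * ab / p   # P - B
    out[:, :, :] = 0.0
    out[0, 0, 0] = math.exp(-mu * ab * ab)
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                # build from (i-1, 0)
                for t in range(i + 1):
                    v = pa * out[i - 1, 0, t]
                    if t > 0:
                        v += out[i - 1, 0, t - 1] / (2.0 * p) * 1.0
                    if t + 1 <= i - 1:
                        v += (t + 1.0) * out[i - 1, 0, t + 1]
                    out[i, 0, t] = v
            else:
                for t in range(i + j + 1):
                    v = pb * out[i, j - 1, t]
                    if t > 0:
                        v += out[i, j - 1, t - 1] / (2.0 * p)
                    if t + 1 <= i + j - 1:
                        v += (t + 1.0) * out[i, j - 1, t + 1]
                    out[i, j, t] = v


@njit(cache=True)
def r_table(tmax, umax, vmax, p, x, y, z, out):
    """Hermite Coulomb integrals R^0_{tuv}(p, P-C) into out[t, u, v]."""
    nmax = tmax + umax + vmax
    r2 = x * x + y * y + z * z
    f = np.empty(nmax + 1)
    boys_fill(nmax, p * r2, f)
    # work[n, t, u, v]
    work = np.zeros((nmax + 1, tmax + 1, umax + 1, vmax + 1))
    fac = 1.0
    for n in range(nmax + 1):
        work[n, 0, 0, 0] = fac * f[n]
        fac *= -2.0 * p
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                if t == 0 and u == 0 and v == 0:
                    continue
                for n in range(nmax - t - u - v, -1, -1):
                    if v > 0:
                        val = z * work[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1.0) * work[n + 1, t, u, v - 2]
                    elif u > 0:
                        val = y * work[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1.0) * work[n + 1, t, u - 2, v]
                    else:
                        val = x * work[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1.0) * work[n + 1, t - 2, u, v]
                    work[n, t, u, v] = val
    out[: tmax + 1, : umax + 1, : vmax + 1] = work[0]


@njit(cache=True)
def one_particle_cart(
    sh_l, sh_coord, sh_pstart, sh_nprim, prim_exp, prim_w,
    sh_cstart, cart_lx, cart_ly, cart_lz,
    pc_pos, pc_chg,
    S, T, V, MX, MY, MZ,
):
    """Overlap, kinetic (mass 1), positive point-charge, and moment matrices
    over Cartesian components of all shells."""
    nsh = sh_l.shape[0]
    ex = np.empty((_NE1, _NE2, _NET))
    ey = np.empty((_NE1, _NE2, _NET))
    ez = np.empty((_NE1, _NE2, _NET))
    npc = pc_chg.shape[0]
    for ish in range(nsh):
        la = sh_l[ish]
        for jsh in range(ish + 1):
            lb = sh_l[jsh]
            abx = sh_coord[ish, 0] - sh_coord[jsh, 0]
            aby = sh_coord[ish, 1] - sh_coord[jsh, 1]
            abz = sh_coord[ish, 2] - sh_coord[jsh, 2]
            nca = (la + 1) * (la + 2) // 2
            ncb = (lb + 1) * (lb + 2) // 2
            blkS = np.zeros((nca, ncb))
            blkT = np.zeros((nca, ncb))
            blkV = np.zeros((nca, ncb))
            blkX = np.zeros((nca, ncb))
            blkY = np.zeros((nca, ncb))
            blkZ = np.zeros((nca, ncb))
            rt = np.empty((_NET, _NET, _NET))
            for pa in range(sh_pstart[ish], sh_pstart[ish] + sh_nprim[ish]):
                a = prim_exp[pa]
                wa = prim_w[pa]
                for pb in range(sh_pstart[jsh], sh_pstart[jsh] + sh_nprim[jsh]):
                    b = prim_exp[pb]
                    w = wa * prim_w[pb]
                    p = a + b
                    e_table(la, lb + 2, a, b, abx, ex)
                    e_table(la, lb + 2, a, b, aby, ey)
                    e_table(la, lb + 2, a, b, abz, ez)
                    sq = math.sqrt(math.pi / p)
                    fx = sq * sq * sq
                    px = (a * sh_coord[ish, 0] + b * sh_coord[jsh, 0]) / p
                    py = (a * sh_coord[ish, 1] + b * sh_coord[jsh, 1]) / p
                    pz = (a * sh_coord[ish, 2] + b * sh_coord[jsh, 2]) / p
                    for ia in range(nca):
                        i1 = cart_lx[sh_cstart[ish] + ia]
                        j1 = cart_ly[sh_cstart[ish] + ia]
                        k1 = cart_lz[sh_cstart[ish] + ia]
                        for ib in range(ncb):
                            i2 = cart_lx[sh_cstart[jsh] + ib]
                            j2 = cart_ly[sh_cstart[jsh] + ib]
                            k2 = cart_lz[sh_cstart[jsh] + ib]
                            sx = ex[i1, i2, 0]
                            sy = ey[j1, j2, 0]
                            sz = ez[k1, k2, 0]
                            blkS[ia, ib] += w * fx * sx * sy * sz
                            # kinetic: 1-D pieces via raised/lowered ket
                            tx = -2.0 * b * b * ex[i1, i2 + 2, 0] \
                                + b * (2.0 * i2 + 1.0) * sx
                            if i2 >= 2:
                                tx -= 0.5 * i2 * (i2 - 1.0) * ex[i1, i2 - 2, 0]
                            ty = -2.0 * b * b * ey[j1, j2 + 2, 0] \
                                + b * (2.0 * j2 + 1.0) * sy
                            if j2 >= 2:
                                ty -= 0.5 * j2 * (j2 - 1.0) * ey[j1, j2 - 2, 0]
                            tz = -2.0 * b * b * ez[k1, k2 + 2, 0] \
                                + b * (2.0 * k2 + 1.0) * sz
                            if k2 >= 2:
                                tz -= 0.5 * k2 * (k2 - 1.0) * ez[k1, k2 - 2, 0]
                            blkT[ia, ib] += w * fx * (
                                tx * sy * sz + sx * ty * sz + sx * sy * tz
                            )
                            # moments about the origin
                            mx = ex[i1, i2, 1] + px * sx
                            my = ey[j1, j2, 1] + py * sy
                            mz = ez[k1, k2, 1] + pz * sz
                            blkX[ia, ib] += w * fx * mx * sy * sz
                            blkY[ia, ib] += w * fx * sx * my * sz
                            blkZ[ia, ib] += w * fx * sx * sy * mz
                    if npc > 0:
                        tmax = la + lb
                        for ic in range(npc):
                            r_table(
                                tmax, tmax, tmax, p,
                                px - pc_pos[ic, 0],
                                py - pc_pos[ic, 1],
                                pz - pc_pos[ic, 2],
                                rt,
                            )
                            pref = w * pc_chg[ic] * 2.0 * math.pi / p
                            for ia in range(nca):
                                i1 = cart_lx[sh_cstart[ish] + ia]
                                j1 = cart_ly[sh_cstart[ish] + ia]
                                k1 = cart_lz[sh_cstart[ish] + ia]
                                for ib in range(ncb):
                                    i2 = cart_lx[sh_cstart[jsh] + ib]
                                    j2 = cart_ly[sh_cstart[jsh] + ib]
                                    k2 = cart_lz[sh_cstart[jsh] + ib]
                                    acc = 0.0
                                    for t in range(i1 + i2 + 1):
                                        for u in range(j1 + j2 + 1):
                                            for v in range(k1 + k2 + 1):
                                                acc += (
                                                    ex[i1, i2, t]
                                                    * ey[j1, j2, u]
                                                    * ez[k1, k2, v]
                                                    * rt[t, u, v]
                                                )
                                    blkV[ia, ib] += pref * acc
            ra = sh_cstart[ish]
            rb = sh_cstart[jsh]
            for ia in range(nca):
                for ib in range(ncb):
                    S[ra + ia, rb + ib] = blkS[ia, ib]
                    S[rb + ib, ra + ia] = blkS[ia, ib]
                    T[ra + ia, rb + ib] = blkT[ia, ib]
                    T[rb + ib, ra + ia] = blkT[ia, ib]
                    V[ra + ia, rb + ib] = blkV[ia, ib]
                    V[rb + ib, ra + ia] = blkV[ia, ib]
                    MX[ra + ia, rb + ib] = blkX[ia, ib]
                    MX[rb + ib, ra + ia] = blkX[ia, ib]
                    MY[ra + ia, rb + ib] = blkY[ia, ib]
                    MY[rb + ib, ra + ia] = blkY[ia, ib]
                    MZ[ra + ia, rb + ib] = blkZ[ia, ib]
                    MZ[rb + ib, ra + ia] = blkZ[ia, ib]


@njit(cache=True)
def _pair_count(sh_nprim):
    nsh = sh_nprim.shape[0]
    npair = 0
    nprimpair = 0
    for i in range(nsh):
        for j in range(i + 1):
            npair += 1
            nprimpair += sh_nprim[i] * sh_nprim[j]
    return npair, nprimpair


@njit(cache=True)
def build_pairs(sh_l, sh_coord, sh_pstart, sh_nprim, prim_exp, prim_w):
    """Precompute per-shell-pair primitive data and Hermite E tables.

    Returns flat arrays describing every (i >= j) shell pair:
    pair_sh[npair, 2], pair_pp_start[npair + 1], and per primitive pair
    pp_p (total exponent), pp_P[, 3] (Gaussian product center) and
    pp_E[, 3, _NE1, _NE1, _NET] (weighted E tables; weight folded into x).
    """
    npair, npp = _pair_count(sh_nprim)
    pair_sh = np.empty((npair, 2), dtype=np.int64)
    pair_pp_start = np.empty(npair + 1, dtype=np.int64)
    pp_p = np.empty(npp)
    pp_P = np.empty((npp, 3))
    pp_E = np.empty((npp, 3, _NE1, _NE1, _NET))
    et = np.empty((_NE1, _NE2, _NET))
    nsh = sh_l.shape[0]
    ip = 0
    kp = 0
    for i in range(nsh):
        for j in range(i + 1):
            pair_sh[ip, 0] = i
            pair_sh[ip, 1] = j
            pair_pp_start[ip] = kp
            la = sh_l[i]
            lb = sh_l[j]
            for pa in range(sh_pstart[i], sh_pstart[i] + sh_nprim[i]):
                a = prim_exp[pa]
                for pb in range(sh_pstart[j], sh_pstart[j] + sh_nprim[j]):
                    b = prim_exp[pb]
                    w = prim_w[pa] * prim_w[pb]
                    p = a + b
                    pp_p[kp] = p
                    for d in range(3):
                        pp_P[kp, d] = (
                            a * sh_coord[i, d] + b * sh_coord[j, d]
                        ) / p
                        e_table(
                            la, lb, a, b,
                            sh_coord[i, d] - sh_coord[j, d], et,
                        )
                        for ii in range(la + 1):
                            for jj in range(lb + 1):
                                for t in range(la + lb + 1):
                                    v = et[ii, jj, t]
                                    if d == 0:
                                        v *= w  # fold weight once
                                    pp_E[kp, d, ii, jj, t] = v
                    kp += 1
            ip += 1
    pair_pp_start[npair] = kp
    return pair_sh, pair_pp_start, pp_p, pp_P, pp_E


@njit(cache=True)
def eri_cart(
    # bra basis
    sh_l1, sh_cstart1, cart_lx1, cart_ly1, cart_lz1,
    pair_sh1, pair_pp_start1, pp_p1, pp_P1, pp_E1,
    # ket basis
    sh_l2, sh_cstart2, cart_lx2, cart_ly2, cart_lz2,
    pair_sh2, pair_pp_start2, pp_p2, pp_P2, pp_E2,
    same_basis,
    out,
):
    """Positive-kernel two-particle Coulomb tensor (ab|cd) over Cartesian
    components; bra and ket may come from different particle species."""
    npair1 = pair_sh1.shape[0]
    npair2 = pair_sh2.shape[0]
    nrt = 4 * LMAX + 1
    rt = np.empty((nrt, nrt, nrt))
    for ipr in range(npair1):
        ish = pair_sh1[ipr, 0]
        jsh = pair_sh1[ipr, 1]
        la = sh_l1[ish]
        lb = sh_l1[jsh]
        nca = (la + 1) * (la + 2) // 2
        ncb = (lb + 1) * (lb + 2) // 2
        lab = la + lb
        jmax = npair2 if same_basis == 0 else ipr + 1
        for jpr in range(jmax):
            ksh = pair_sh2[jpr, 0]
            lsh = pair_sh2[jpr, 1]
            lc = sh_l2[ksh]
            ld = sh_l2[lsh]
            ncc = (lc + 1) * (lc + 2) // 2
            ncd = (ld + 1) * (ld + 2) // 2
            lcd = lc + ld
            blk = np.zeros((nca, ncb, ncc, ncd))
            # g[tuv (bra), ic, id] intermediate
            g = np.zeros((lab + 1, lab + 1, lab + 1, ncc, ncd))
            for kp in range(pair_pp_start1[ipr], pair_pp_start1[ipr + 1]):
                p = pp_p1[kp]
                g[:, :, :, :, :] = 0.0
                for lq in range(pair_pp_start2[jpr], pair_pp_start2[jpr + 1]):
                    q = pp_p2[lq]
                    alpha = p * q / (p + q)
                    pref = (
                        2.0 * math.pow(math.pi, 2.5)
                        / (p * q * math.sqrt(p + q))
                    )
                    r_table(
                        lab + lcd, lab + lcd, lab + lcd, alpha,
                        pp_P1[kp, 0] - pp_P2[lq, 0],
                        pp_P1[kp, 1] - pp_P2[lq, 1],
                        pp_P1[kp, 2] - pp_P2[lq, 2],
                        rt,
                    )
                    for ic in range(ncc):
                        i3 = cart_lx2[sh_cstart2[ksh] + ic]
                        j3 = cart_ly2[sh_cstart2[ksh] + ic]
                        k3 = cart_lz2[sh_cstart2[ksh] + ic]
                        for idx in range(ncd):
                            i4 = cart_lx2[sh_cstart2[lsh] + idx]
                            j4 = cart_ly2[sh_cstart2[lsh] + idx]
                            k4 = cart_lz2[sh_cstart2[lsh] + idx]
                            for t in range(lab + 1):
                                for u in range(lab + 1):
                                    for v in range(lab + 1):
                                        acc = 0.0
                                        for tp in range(i3 + i4 + 1):
                                            etp = pp_E2[lq, 0, i3, i4, tp]
                                            if etp == 0.0:
                                                continue
                                            for up in range(j3 + j4 + 1):
                                                eup = pp_E2[lq, 1, j3, j4, up]
                                                if eup == 0.0:
                                                    continue
                                                for vp in range(k3 + k4 + 1):
                                                    evp = pp_E2[
                                                        lq, 2, k3, k4, vp
                                                    ]
                                                    if evp == 0.0:
                                                        continue
                                                    sgn = 1.0
                                                    if (tp + up + vp) % 2 == 1:
                                                        sgn = -1.0
                                                    acc += (
                                                        sgn * etp * eup * evp
                                                        * rt[t + tp, u + up,
                                                             v + vp]
                                                    )
                                        g[t, u, v, ic, idx] += pref * acc
                # contract bra E coefficients
                for ia in range(nca):
                    i1 = cart_lx1[sh_cstart1[ish] + ia]
                    j1 = cart_ly1[sh_cstart1[ish] + ia]
                    k1 = cart_lz1[sh_cstart1[ish] + ia]
                    for ib in range(ncb):
                        i2 = cart_lx1[sh_cstart1[jsh] + ib]
                        j2 = cart_ly1[sh_cstart1[jsh] + ib]
                        k2 = cart_lz1[sh_cstart1[jsh] + ib]
                        for ic in range(ncc):
                            for idx in range(ncd):
                                acc = 0.0
                                for t in range(i1 + i2 + 1):
                                    e1 = pp_E1[kp, 0, i1, i2, t]
                                    if e1 == 0.0:
                                        continue
                                    for u in range(j1 + j2 + 1):
                                        e2 = pp_E1[kp, 1, j1, j2, u]
                                        if e2 == 0.0:
                                            continue
                                        for v in range(k1 + k2 + 1):
                                            e3 = pp_E1[kp, 2, k1, k2, v]
                                            if e3 == 0.0:
                                                continue
                                            acc += (
                                                e1 * e2 * e3
                                                * g[t, u, v, ic, idx]
                                            )
                                blk[ia, ib, ic, idx] += acc
            # scatter block with full permutational symmetry
            ra = sh_cstart1[ish]
            rb = sh_cstart1[jsh]
            rc = sh_cstart2[ksh]
            rd = sh_cstart2[lsh]
            for ia in range(nca):
                for ib in range(ncb):
                    for ic in range(ncc):
                        for idx in range(ncd):
                            v = blk[ia, ib, ic, idx]
                            m1 = ra + ia
                            m2 = rb + ib
                            m3 = rc + ic
                            m4 = rd + idx
                            out[m1, m2, m3, m4] = v
                            out[m2, m1, m3, m4] = v
                            out[m1, m2, m4, m3] = v
                            out[m2, m1, m4, m3] = v
                            if same_basis == 1:
                                out[m3, m4, m1, m2] = v
                                out[m4, m3, m1, m2] = v
                                out[m3, m4, m2, m1] = v
                                out[m4, m3, m2, m1] = v
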