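"""McMurchie-Davidson Gaussian integrals (numba-jitted kernels).

Supports Cartesian shells with l <= 2.  Provides overlap/kinetic/nuclear
matrices, two-electron repulsion integrals, the analytic Coulomb potential
of a density matrix at arbitrary points, and electron-repulsion energies.

Conventions: primitives carry their (l,0,0) normalization folded into the
contraction coefficients (see basis.py); per-component normalization factors
are applied when scattering shell blocks into AO matrices.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LMAX = 2
# Cartesian components per l, Molden order, flattened with offsets.
_CART_LX = np.array([0, 1, 0, 0, 2, 0, 0, 1, 1, 0], dtype=np.int64)
_CART_LY = np.array([0, 0, 1, 0, 0, 2, 0, 1, 0, 1], dtype=np.int64)
_CART_LZ = np.array([0, 0, 0, 1, 0, 0, 2, 0, 1, 1], dtype=np.int64)
_L_OFF = np.array([0, 1, 4], dtype=np.int64)
_L_NCART = np.array([1, 3, 6], dtype=np.int64)


import math


@njit(cache=False)
def _boys(mmax, T, out):
    """Boys function F_m(T) for m = 0..mmax."""
    if T > 13.0:
        # erf closed form for F_0, stable upward recursion (2T > 2m+1 here)
        sT = np.sqrt(T)
        out[0] = 0.5 * np.sqrt(np.pi) * math.erf(sT) / sT
        expT = np.exp(-T) if T < 38.0 else 0.0
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - expT) / (2.0 * T)
        return
    # convergent series for F_mmax, then downward recursion
    n = mmax
    term = 1.0 / (2 * n + 1)
    s = term
    k = 0
    while term > 1e-17 * s:
        term *= 2.0 * T / (2 * n + 2 * k + 3)
        s += term
        k += 1
    expT = np.exp(-T)
    out[n] = expT * s
    for m in range(n - 1, -1, -1):
        out[m] = (2.0 * T * out[m + 1] + expT) / (2 * m + 1)


@njit(cache=False)
def _fill_E(la, lb, PA, PB, p, Kdim, E):
    """Hermite expansion coefficients E[i,j,t] for one Cartesian direction.

    E[0,0,0] carries the dimension's Gaussian-product prefactor ``Kdim``.
    """
    oo2p = 0.5 / p
    for i in range(E.shape[0]):
        for j in range(E.shape[1]):
            for t in range(E.shape[2]):
                E[i, j, t] = 0.0
    E[0, 0, 0] = Kdim
    for i in range(la):
        for t in range(i + 2):
            v = PA * E[i, 0, t]
            if t > 0:
                v += oo2p * E[i, 0, t - 1]
            if t + 1 <= i:
                v += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for i in range(la + 1):
        for j in range(lb):
            for t in range(i + j + 2):
                v = PB * E[i, j, t]
                if t > 0:
                    v += oo2p * E[i, j, t - 1]
                if t + 1 <= i + j:
                    v += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = v


@njit(cache=False)
def _fill_R(L, p, X, Y, Z, Fm, R, W):
    """Hermite Coulomb integrals R_{tuv} (n=0) up to t+u+v = L.

    ``R`` has shape (L+1, L+1, L+1); ``W`` is a preallocated 4D scratch of
    shape at least (L+1, L+1, L+1, L+1) for the auxiliary-index recursion.
    """
    fac = 1.0
    for n in range(L + 1):
        W[n, 0, 0, 0] = fac * Fm[n]
        fac *= -2.0 * p
    for ttot in range(1, L + 1):
        for t in range(ttot + 1):
            for u in range(ttot - t + 1):
                v = ttot - t - u
                for n in range(L - ttot + 1):
                    if t >= 1:
                        val = X * W[n + 1, t - 1, u, v]
                        if t >= 2:
                            val += (t - 1) * W[n + 1, t - 2, u, v]
                    elif u >= 1:
                        val = Y * W[n + 1, t, u - 1, v]
                        if u >= 2:
                            val += (u - 1) * W[n + 1, t, u - 2, v]
                    else:
                        val = Z * W[n + 1, t, u, v - 1]
                        if v >= 2:
                            val += (v - 1) * W[n + 1, t, u, v - 2]
                    W[n, t, u, v] = val
    for t in range(L + 1):
        for u in range(L + 1 - t):
            for v in range(L + 1 - t - u):
                R[t, u, v] = W[0, t, u, v]


@njit(cache=False)
def _build_pairs(shell_l, shell_center, shell_pstart, shell_nprim, prim_exp, prim_coef):
    """Primitive-pair tables for all canonical shell pairs (i >= j).

    Returns per-shell-pair index arrays and per-primitive-pair data:
    total exponent p, Gaussian-product center P, coefficient product
    (with the pair's Gaussian prefactor folded into the E tables), and
    E tables of fixed stride (3, LMAX+1, LMAX+1, 2*LMAX+1).
    """
    ns = len(shell_l)
    npair = ns * (ns + 1) // 2
    pair_i = np.empty(npair, dtype=np.int64)
    pair_j = np.empty(npair, dtype=np.int64)
    counts = np.empty(npair, dtype=np.int64)
    idx = 0
    total_pp = 0
    for i in range(ns):
        for j in range(i + 1):
            pair_i[idx] = i
            pair_j[idx] = j
            counts[idx] = shell_nprim[i] * shell_nprim[j]
            total_pp += counts[idx]
            idx += 1
    pp_start = np.zeros(npair + 1, dtype=np.int64)
    for k in range(npair):
        pp_start[k + 1] = pp_start[k] + counts[k]
    pp_p = np.empty(total_pp)
    pp_P = np.empty((total_pp, 3))
    pp_cc = np.empty(total_pp)
    estride = (LMAX + 1) * (LMAX + 1) * (2 * LMAX + 1)
    pp_E = np.zeros((total_pp, 3, LMAX + 1, LMAX + 1, 2 * LMAX + 1))
    Etmp = np.zeros((LMAX + 1, LMAX + 1, 2 * LMAX + 1))
    for k in range(npair):
        i = pair_i[k]
        j = pair_j[k]
        la = shell_l[i]
        lb = shell_l[j]
        A = shell_center[i]
        B = shell_center[j]
        pos = pp_start[k]
        for pa in range(shell_nprim[i]):
            a = prim_exp[shell_pstart[i] + pa]
            ca = prim_coef[shell_pstart[i] + pa]
            for pb in range(shell_nprim[j]):
                b = prim_exp[shell_pstart[j] + pb]
                cb = prim_coef[shell_pstart[j] + pb]
                p = a + b
                mu = a * b / p
                pp_p[pos] = p
                pp_cc[pos] = ca * cb
                for d in range(3):
                    pp_P[pos, d] = (a * A[d] + b * B[d]) / p
                for d in range(3):
                    Xab = A[d] - B[d]
                    Kdim = np.exp(-mu * Xab * Xab)
                    _fill_E(la, lb, pp_P[pos, d] - A[d], pp_P[pos, d] - B[d], p, Kdim, Etmp)
                    for ii in range(LMAX + 1):
                        for jj in range(LMAX + 1):
                            for tt in range(2 * LMAX + 1):
                                pp_E[pos, d, ii, jj, tt] = Etmp[ii, jj, tt]
                pos += 1
    return pair_i, pair_j, pp_start, pp_p, pp_P, pp_cc, pp_E


@njit(cache=False)
def _overlap_kinetic(shell_l, shell_center, shell_pstart, shell_nprim,
                     prim_exp, prim_coef, shell_cart_start, comp_norm, nao):
    """Overlap and kinetic-energy matrices over Cartesian AOs."""
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    ns = len(shell_l)
    # E tables with lb extended by 2 for the kinetic 1D formula
    E = np.zeros((3, LMAX + 1, LMAX + 3, 2 * LMAX + 3))
    Etmp = np.zeros((LMAX + 1, LMAX + 3, 2 * LMAX + 3))
    for i in range(ns):
        for j in range(i + 1):
            la = shell_l[i]
            lb = shell_l[j]
            A = shell_center[i]
            B = shell_center[j]
            oa = shell_cart_start[i]
            ob = shell_cart_start[j]
            na = _L_NCART[la]
            nb = _L_NCART[lb]
            Sblk = np.zeros((na, nb))
            Tblk = np.zeros((na, nb))
            for pa in range(shell_nprim[i]):
                a = prim_exp[shell_pstart[i] + pa]
                ca = prim_coef[shell_pstart[i] + pa]
                for pb in range(shell_nprim[j]):
                    b = prim_exp[shell_pstart[j] + pb]
                    cb = prim_coef[shell_pstart[j] + pb]
                    p = a + b
                    mu = a * b / p
                    sq = np.sqrt(np.pi / p)
                    for d in range(3):
                        Xab = A[d] - B[d]
                        P = (a * A[d] + b * B[d]) / p
                        _fill_E(la, lb + 2, P - A[d], P - B[d], p, np.exp(-mu * Xab * Xab), Etmp)
                        for ii in range(LMAX + 1):
                            for jj in range(LMAX + 3):
                                for tt in range(2 * LMAX + 3):
                                    E[d, ii, jj, tt] = Etmp[ii, jj, tt]
                    cc = ca * cb
                    for caidx in range(na):
                        ax = _CART_LX[_L_OFF[la] + caidx]
                        ay = _CART_LY[_L_OFF[la] + caidx]
                        az = _CART_LZ[_L_OFF[la] + caidx]
                        for cbidx in range(nb):
                            bx = _CART_LX[_L_OFF[lb] + cbidx]
                            by = _CART_LY[_L_OFF[lb] + cbidx]
                            bz = _CART_LZ[_L_OFF[lb] + cbidx]
                            s1 = E[0, ax, bx, 0] * sq
                            s2 = E[1, ay, by, 0] * sq
                            s3 = E[2, az, bz, 0] * sq
                            # 1D kinetic parts
                            k1 = -2.0 * b * b * E[0, ax, bx + 2, 0] * sq \
                                + b * (2 * bx + 1) * s1
                            if bx >= 2:
                                k1 -= 0.5 * bx * (bx - 1) * E[0, ax, bx - 2, 0] * sq
                            k2 = -2.0 * b * b * E[1, ay, by + 2, 0] * sq \
                                + b * (2 * by + 1) * s2
                            if by >= 2:
                                k2 -= 0.5 * by * (by - 1) * E[1, ay, by - 2, 0] * sq
                            k3 = -2.0 * b * b * E[2, az, bz + 2, 0] * sq \
                                + b * (2 * bz + 1) * s3
                            if bz >= 2:
                                k3 -= 0.5 * bz * (bz - 1) * E[2, az, bz - 2, 0] * sq
                            Sblk[caidx, cbidx] += cc * s1 * s2 * s3
                            Tblk[caidx, cbidx] += cc * (k1 * s2 * s3 + s1 * k2 * s3 + s1 * s2 * k3)
            for caidx in range(na):
                fa = comp_norm[oa + caidx]
                for cbidx in range(nb):
                    fb = comp_norm[ob + cbidx]
                    S[oa + caidx, ob + cbidx] = fa * fb * Sblk[caidx, cbidx]
                    S[ob + cbidx, oa + caidx] = S[oa + caidx, ob + cbidx]
                    T[oa + caidx, ob + cbidx] = fa * fb * Tblk[caidx, cbidx]
                    T[ob + cbidx, oa + caidx] = T[oa + caidx, ob + cbidx]
    return S, T


@njit(cache=False)
def _attraction(shell_l, shell_cart_start, comp_norm, nao,
                pair_i, pair_j, pp_start, pp_p, pp_P, pp_cc, pp_E,
                centers, charges):
    """V[a,b] = sum_C -q_C <a| 1/|r-C| |b> over Cartesian AOs."""
    V = np.zeros((nao, nao))
    Fm = np.zeros(2 * LMAX + 1)
    R = np.zeros((2 * LMAX + 1, 2 * LMAX + 1, 2 * LMAX + 1))
    W = np.zeros((2 * LMAX + 1, 2 * LMAX + 1, 2 * LMAX + 1, 2 * LMAX + 1))
    npair = len(pair_i)
    nc = len(charges)
    for k in range(npair):
        i = pair_i[k]
        j = pair_j[k]
        la = shell_l[i]
        lb = shell_l[j]
        L = la + lb
        oa = shell_cart_start[i]
        ob = shell_cart_start[j]
        na = _L_NCART[la]
        nb = _L_NCART[lb]
        Vblk = np.zeros((na, nb))
        for pp in range(pp_start[k], pp_start[k + 1]):
            p = pp_p[pp]
            cc = pp_cc[pp]
            pref = cc * 2.0 * np.pi / p
            for ci in range(nc):
                X = pp_P[pp, 0] - centers[ci, 0]
                Y = pp_P[pp, 1] - centers[ci, 1]
                Z = pp_P[pp, 2] - centers[ci, 2]
                T = p * (X * X + Y * Y + Z * Z)
                _boys(L, T, Fm)
                _fill_R(L, p, X, Y, Z, Fm, R, W)
                q = -charges[ci] * pref
                for caidx in range(na):
                    ax = _CART_LX[_L_OFF[la] + caidx]
                    ay = _CART_LY[_L_OFF[la] + caidx]
                    az = _CART_LZ[_L_OFF[la] + caidx]
                    for cbidx in range(nb):
                        bx = _CART_LX[_L_OFF[lb] + cbidx]
                        by = _CART_LY[_L_OFF[lb] + cbidx]
                        bz = _CART_LZ[_L_OFF[lb] + cbidx]
                        acc = 0.0
                        for t in range(ax + bx + 1):
                            for u in range(ay + by + 1):
                                for v in range(az + bz + 1):
                                    acc += (pp_E[pp, 0, ax, bx, t]
                                            * pp_E[pp, 1, ay, by, u]
                                            * pp_E[pp, 2, az, bz, v]
                                            * R[t, u, v])
                        Vblk[caidx, cbidx] += q * acc
        for caidx in range(na):
            fa = comp_norm[oa + caidx]
            for cbidx in range(nb):
                fb = comp_norm[ob + cbidx]
                V[oa + caidx, ob + cbidx] = fa * fb * Vblk[caidx, cbidx]
                V[ob + cbidx, oa + caidx] = V[oa + caidx, ob + cbidx]
    return V


@njit(cache=False)
def _eri(shell_l, shell_cart_start, comp_norm, nao,
         pair_i, pair_j, pp_start, pp_p, pp_P, pp_cc, pp_E):
    """Full two-electron repulsion tensor (chemists' notation (ab|cd))."""
    eri = np.zeros((nao, nao, nao, nao))
    npair = len(pair_i)
    LT = 4 * LMAX
    Fm = np.zeros(LT + 1)
    R = np.zeros((LT + 1, LT + 1, LT + 1))
    W = np.zeros((LT + 1, LT + 1, LT + 1, LT + 1))
    for kab in range(npair):
        i = pair_i[kab]
        j = pair_j[kab]
        la = shell_l[i]
        lb = shell_l[j]
        oa = shell_cart_start[i]
        ob = shell_cart_start[j]
        na = _L_NCART[la]
        nb = _L_NCART[lb]
        for kcd in range(kab + 1):
            c = pair_i[kcd]
            d = pair_j[kcd]
            lc = shell_l[c]
            ld = shell_l[d]
            oc = shell_cart_start[c]
            od = shell_cart_start[d]
            ncc = _L_NCART[lc]
            nd = _L_NCART[ld]
            L = la + lb + lc + ld
            blk = np.zeros((na, nb, ncc, nd))
            for ppab in range(pp_start[kab], pp_start[kab + 1]):
                p = pp_p[ppab]
                ccab = pp_cc[ppab]
                if abs(ccab) * abs(pp_E[ppab, 0, 0, 0, 0] * pp_E[ppab, 1, 0, 0, 0] * pp_E[ppab, 2, 0, 0, 0]) < 1e-16:
                    continue
                for ppcd in range(pp_start[kcd], pp_start[kcd + 1]):
                    q = pp_p[ppcd]
                    cccd = pp_cc[ppcd]
                    if abs(cccd) * abs(pp_E[ppcd, 0, 0, 0, 0] * pp_E[ppcd, 1, 0, 0, 0] * pp_E[ppcd, 2, 0, 0, 0]) < 1e-16:
                        continue
                    alpha = p * q / (p + q)
                    X = pp_P[ppab, 0] - pp_P[ppcd, 0]
                    Y = pp_P[ppab, 1] - pp_P[ppcd, 1]
                    Z = pp_P[ppab, 2] - pp_P[ppcd, 2]
                    T = alpha * (X * X + Y * Y + Z * Z)
                    _boys(L, T, Fm)
                    _fill_R(L, alpha, X, Y, Z, Fm, R, W)
                    pref = ccab * cccd * 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                    for ca in range(na):
                        ax = _CART_LX[_L_OFF[la] + ca]
                        ay = _CART_LY[_L_OFF[la] + ca]
                        az = _CART_LZ[_L_OFF[la] + ca]
                        for cb in range(nb):
                            bx = _CART_LX[_L_OFF[lb] + cb]
                            by = _CART_LY[_L_OFF[lb] + cb]
                            bz = _CART_LZ[_L_OFF[lb] + cb]
                            for cc2 in range(ncc):
                                cx = _CART_LX[_L_OFF[lc] + cc2]
                                cy = _CART_LY[_L_OFF[lc] + cc2]
                                cz = _CART_LZ[_L_OFF[lc] + cc2]
                                for cd2 in range(nd):
                                    dx = _CART_LX[_L_OFF[ld] + cd2]
                                    dy = _CART_LY[_L_OFF[ld] + cd2]
                                    dz = _CART_LZ[_L_OFF[ld] + cd2]
                                    acc = 0.0
                                    for t in range(ax + bx + 1):
                                        Ex1 = pp_E[ppab, 0, ax, bx, t]
                                        for u in range(ay + by + 1):
                                            Exy1 = Ex1 * pp_E[ppab, 1, ay, by, u]
                                            for v in range(az + bz + 1):
                                                E1 = Exy1 * pp_E[ppab, 2, az, bz, v]
                                                acc2 = 0.0
                                                for tt in range(cx + dx + 1):
                                                    Ex2 = pp_E[ppcd, 0, cx, dx, tt]
                                                    for uu in range(cy + dy + 1):
                                                        Exy2 = Ex2 * pp_E[ppcd, 1, cy, dy, uu]
                                                        for vv in range(cz + dz + 1):
                                                            sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                            acc2 += sgn * Exy2 * pp_E[ppcd, 2, cz, dz, vv] \
                                                                * R[t + tt, u + uu, v + vv]
                                                acc += E1 * acc2
                                    blk[ca, cb, cc2, cd2] += pref * acc
            for ca in range(na):
                A = oa + ca
                fa = comp_norm[A]
                for cb in range(nb):
                    B = ob + cb
                    fb = comp_norm[B]
                    for cc2 in range(ncc):
                        C = oc + cc2
                        fc = comp_norm[C]
                        for cd2 in range(nd):
                            D = od + cd2
                            fd = comp_norm[D]
                            val = fa * fb * fc * fd * blk[ca, cb, cc2, cd2]
                            eri[A, B, C, D] = val
                            eri[B, A, C, D] = val
                            eri[A, B, D, C] = val
                            eri[B, A, D, C] = val
                            eri[C, D, A, B] = val
                            eri[D, C, A, B] = val
                            eri[C, D, B, A] = val
                            eri[D, C, B, A] = val
    return eri


@njit(cache=False)
def _hermite_density(shell_l, shell_cart_start, comp_norm,
                     pair_i, pair_j, pp_start, pp_p, pp_P, pp_cc, pp_E,
                     D):
    """Hermite-space representation of a density matrix.

    Contracting the density matrix with the E tables once gives, per
    primitive pair, coefficients H_{tuv} such that the Coulomb potential at
    a point reduces to sum_tuv H_tuv R_tuv — cost per grid point is then
    linear in the number of primitive pairs.
    """
    npair = len(pair_i)
    HS = (2 * LMAX + 1) ** 3
    npp = len(pp_p)
    H = np.zeros((npp, HS))
    Lpp = np.zeros(npp, dtype=np.int64)
    keep = np.zeros(npp, dtype=np.int64)
    for k in range(npair):
        i = pair_i[k]
        j = pair_j[k]
        la = shell_l[i]
        lb = shell_l[j]
        oa = shell_cart_start[i]
        ob = shell_cart_start[j]
        na = _L_NCART[la]
        nb = _L_NCART[lb]
        L = la + lb
        sym = 1.0 if i == j else 2.0
        for pp in range(pp_start[k], pp_start[k + 1]):
            cc = pp_cc[pp]
            Lpp[pp] = L
            hmax = 0.0
            for ca in range(na):
                ax = _CART_LX[_L_OFF[la] + ca]
                ay = _CART_LY[_L_OFF[la] + ca]
                az = _CART_LZ[_L_OFF[la] + ca]
                for cb in range(nb):
                    bx = _CART_LX[_L_OFF[lb] + cb]
                    by = _CART_LY[_L_OFF[lb] + cb]
                    bz = _CART_LZ[_L_OFF[lb] + cb]
                    dv = sym * cc * comp_norm[oa + ca] * comp_norm[ob + cb] * D[oa + ca, ob + cb]
                    if dv == 0.0:
                        continue
                    for t in range(ax + bx + 1):
                        for u in range(ay + by + 1):
                            for v in range(az + bz + 1):
                                idx = (t * (2 * LMAX + 1) + u) * (2 * LMAX + 1) + v
                                H[pp, idx] += dv * (pp_E[pp, 0, ax, bx, t]
                                                    * pp_E[pp, 1, ay, by, u]
                                                    * pp_E[pp, 2, az, bz, v])
            for idx in range(HS):
                if abs(H[pp, idx]) > hmax:
                    hmax = abs(H[pp, idx])
            keep[pp] = 1 if hmax > 1e-14 else 0
    return H, Lpp, keep


@njit(cache=False)
def _potential_at_points(pp_p, pp_P, H, Lpp, keep, points):
    """v(r_g) = sum_pp (2 pi / p) sum_tuv H_tuv R_tuv(p, P - r_g)."""
    M = len(points)
    out = np.zeros(M)
    Fm = np.zeros(2 * LMAX + 1)
    R = np.zeros((2 * LMAX + 1, 2 * LMAX + 1, 2 * LMAX + 1))
    W = np.zeros((2 * LMAX + 1, 2 * LMAX + 1, 2 * LMAX + 1, 2 * LMAX + 1))
    npp = len(pp_p)
    sqpi = np.sqrt(np.pi)
    for g in range(M):
        x = points[g, 0]
        y = points[g, 1]
        z = points[g, 2]
        acc = 0.0
        for pp in range(npp):
            if keep[pp] == 0:
                continue
            p = pp_p[pp]
            X = pp_P[pp, 0] - x
            Y = pp_P[pp, 1] - y
            Z = pp_P[pp, 2] - z
            T = p * (X * X + Y * Y + Z * Z)
            L = Lpp[pp]
            if L == 0:
                # s|s pair: v = H_000 (2 pi / p) F_0(T), F_0 via erf
                if T < 1e-14:
                    F0 = 1.0 - T / 3.0
                else:
                    sT = np.sqrt(T)
                    F0 = 0.5 * sqpi * math.erf(sT) / sT
                acc += H[pp, 0] * F0 * 2.0 * np.pi / p
                continue
            _boys(L, T, Fm)
            _fill_R(L, p, X, Y, Z, Fm, R, W)
            s = 0.0
            for t in range(L + 1):
                for u in range(L + 1 - t):
                    for v in range(L + 1 - t - u):
                        idx = (t * (2 * LMAX + 1) + u) * (2 * LMAX + 1) + v
                        s += H[pp, idx] * R[t, u, v]
            acc += s * 2.0 * np.pi / p
        out[g] = acc
    return out


# ---------------------------------------------------------------------------
# Python-facing wrappers over a MoleculeBasis


class IntegralEngine:
    """Caches primitive-pair tables for one molecular basis."""

    def __init__(self, basis):
        self.basis = basis
        self.comp_norm = np.concatenate(basis.comp_norms)
        (self.pair_i, self.pair_j, self.pp_start, self.pp_p,
         self.pp_P, self.pp_cc, self.pp_E) = _build_pairs(
            basis.shell_l, basis.shell_center, basis.shell_pstart,
            basis.shell_nprim, basis.prim_exp, basis.prim_coef)

    def overlap_kinetic(self):
        return _overlap_kinetic(
            self.basis.shell_l, self.basis.shell_center, self.basis.shell_pstart,
            self.basis.shell_nprim, self.basis.prim_exp, self.basis.prim_coef,
            self.basis.shell_cart_start, self.comp_norm, self.basis.nao_cart)

    def nuclear_attraction(self, centers, charges):
        return _attraction(
            self.basis.shell_l, self.basis.shell_cart_start, self.comp_norm,
            self.basis.nao_cart, self.pair_i, self.pair_j, self.pp_start,
            self.pp_p, self.pp_P, self.pp_cc, self.pp_E,
            np.asarray(centers, dtype=float), np.asarray(charges, dtype=float))

    def eri(self):
        return _eri(
            self.basis.shell_l, self.basis.shell_cart_start, self.comp_norm,
            self.basis.nao_cart, self.pair_i, self.pair_j, self.pp_start,
            self.pp_p, self.pp_P, self.pp_cc, self.pp_E)

    def coulomb_potential(self, dm_cart, points):
        """Analytic v_Coul[rho](r) at ``points`` for a Cartesian density matrix."""
        H, Lpp, keep = _hermite_density(
            self.basis.shell_l, self.basis.shell_cart_start, self.comp_norm,
            self.pair_i, self.pair_j, self.pp_start, self.pp_p, self.pp_P,
            self.pp_cc, self.pp_E, np.ascontiguousarray(dm_cart))
        return _potential_at_points(self.pp_p, self.pp_P, H, Lpp, keep,
                                    np.ascontiguousarray(points, dtype=float))
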