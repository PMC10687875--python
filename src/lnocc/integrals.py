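"""McMurchie–Davidson Gaussian integral engine.

Provides overlap, kinetic, nuclear-attraction and Cartesian multipole
one-electron integrals plus the two- and three-center Coulomb integrals
needed for density fitting.  Hot kernels are JIT-compiled with numba;
cheap one-electron integrals are driven from Python.

All integrals are over *Cartesian* Gaussians (the bases shipped with the
package use s/p orbital functions and up to d auxiliary functions).
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

from .basis import AOBasis, _cart_components

__all__ = ["overlap", "kinetic", "nuclear_attraction", "multipole",
           "eri_2c", "eri_3c"]

_LMAX = 4  # table size bound for Cartesian component lookup


# ----------------------------------------------------------------- kernels

@njit(cache=False)
def _boys(mmax, T, out):
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if T > 35.0:
        out[0] = 0.5 * math.sqrt(math.pi / T)
        emt = math.exp(-T)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - emt) / (2 * T)
        return
    # series at the highest order, then downward recursion (stable)
    emt = math.exp(-T)
    term = 1.0 / (2 * mmax + 1)
    s = term
    k = 1
    while True:
        term *= 2 * T / (2 * mmax + 2 * k + 1)
        s += term
        if term < 1e-17 * s or k > 200:
            break
        k += 1
    out[mmax] = emt * s
    for m in range(mmax - 1, -1, -1):
        out[m] = (2 * T * out[m + 1] + emt) / (2 * m + 1)


@njit(cache=False)
def _e_table(la, lb, p, XPA, XPB):
    """Hermite expansion coefficients E_t^{ij} for one Cartesian direction.

    The Gaussian-product prefactor exp(-mu*X_AB^2) is applied by the caller.
    """
    e = np.zeros((la + 1, lb + 1, la + lb + 2))
    e[0, 0, 0] = 1.0
    inv2p = 0.5 / p
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            for t in range(i + j + 1):
                if j == 0:
                    v = XPA * e[i - 1, 0, t]
                    if t > 0:
                        v += inv2p * e[i - 1, 0, t - 1]
                    v += (t + 1) * e[i - 1, 0, t + 1]
                else:
                    v = XPB * e[i, j - 1, t]
                    if t > 0:
                        v += inv2p * e[i, j - 1, t - 1]
                    v += (t + 1) * e[i, j - 1, t + 1]
                e[i, j, t] = v
    return e


@njit(cache=False)
def _r_tensor(lmax, alpha, X, Y, Z):
    """Hermite Coulomb integrals R_{tuv} (order-0 slice), t+u+v <= lmax."""
    N = lmax
    T = alpha * (X * X + Y * Y + Z * Z)
    F = np.zeros(N + 1)
    _boys(N, T, F)
    R = np.zeros((N + 1, lmax + 1, lmax + 1, lmax + 1))
    f = 1.0
    for n in range(N + 1):
        R[n, 0, 0, 0] = f * F[n]
        f *= -2.0 * alpha
    for t in range(lmax + 1):
        for u in range(lmax + 1 - t):
            for v in range(lmax + 1 - t - u):
                if t == 0 and u == 0 and v == 0:
                    continue
                for n in range(N - (t + u + v) + 1):
                    if t > 0:
                        val = X * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


@njit(cache=False)
def _nuclear_kernel(sh_L, sh_center, sh_ptr, prim_exp, prim_coef, sh_off,
                    comp_lx, comp_ly, comp_lz, ncart_l, zs, coords, out):
    nsh = len(sh_L)
    natm = len(zs)
    for ish in range(nsh):
        la = sh_L[ish]
        A = sh_center[ish]
        for jsh in range(ish + 1):
            lb = sh_L[jsh]
            B = sh_center[jsh]
            nca, ncb = ncart_l[la], ncart_l[lb]
            block = np.zeros((nca, ncb))
            ab2 = 0.0
            for d in range(3):
                ab2 += (A[d] - B[d]) ** 2
            for ip in range(sh_ptr[ish], sh_ptr[ish + 1]):
                a = prim_exp[ip]
                ca = prim_coef[ip]
                for jp in range(sh_ptr[jsh], sh_ptr[jsh + 1]):
                    b = prim_exp[jp]
                    cb = prim_coef[jp]
                    p = a + b
                    kab = math.exp(-a * b / p * ab2)
                    if kab < 1e-16:
                        continue
                    pre = kab * 2.0 * math.pi / p
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    ex = _e_table(la, lb, p, Px - A[0], Px - B[0])
                    ey = _e_table(la, lb, p, Py - A[1], Py - B[1])
                    ez = _e_table(la, lb, p, Pz - A[2], Pz - B[2])
                    for ic in range(natm):
                        R = _r_tensor(la + lb, p, Px - coords[ic, 0],
                                      Py - coords[ic, 1], Pz - coords[ic, 2])
                        w = -zs[ic] * pre * ca * cb
                        for ka in range(nca):
                            lxa = comp_lx[la, ka]
                            lya = comp_ly[la, ka]
                            lza = comp_lz[la, ka]
                            for kb in range(ncb):
                                lxb = comp_lx[lb, kb]
                                lyb = comp_ly[lb, kb]
                                lzb = comp_lz[lb, kb]
                                s = 0.0
                                for t in range(lxa + lxb + 1):
                                    for u in range(lya + lyb + 1):
                                        for v in range(lza + lzb + 1):
                                            s += (ex[lxa, lxb, t]
                                                  * ey[lya, lyb, u]
                                                  * ez[lza, lzb, v]
                                                  * R[t, u, v])
                                block[ka, kb] += w * s
            oa, ob = sh_off[ish], sh_off[jsh]
            for ka in range(nca):
                for kb in range(ncb):
                    out[oa + ka, ob + kb] += block[ka, kb]
                    if ish != jsh:
                        out[ob + kb, oa + ka] += block[ka, kb]


@njit(cache=False)
def _eri3c_kernel(sh_L, sh_center, sh_ptr, prim_exp, prim_coef, sh_off,
                  xL, xcenter, xptr, xexp, xcoef, xoff,
                  comp_lx, comp_ly, comp_lz, ncart_l, out):
    nsh = len(sh_L)
    nxs = len(xL)
    for ish in range(nsh):
        la = sh_L[ish]
        A = sh_center[ish]
        for jsh in range(ish + 1):
            lb = sh_L[jsh]
            B = sh_center[jsh]
            nca, ncb = ncart_l[la], ncart_l[lb]
            ab2 = 0.0
            for d in range(3):
                ab2 += (A[d] - B[d]) ** 2
            for ip in range(sh_ptr[ish], sh_ptr[ish + 1]):
                a = prim_exp[ip]
                ca = prim_coef[ip]
                for jp in range(sh_ptr[jsh], sh_ptr[jsh + 1]):
                    b = prim_exp[jp]
                    cb = prim_coef[jp]
                    p = a + b
                    kab = math.exp(-a * b / p * ab2)
                    if kab * ca * cb == 0.0 or kab < 1e-16:
                        continue
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    ex = _e_table(la, lb, p, Px - A[0], Px - B[0])
                    ey = _e_table(la, lb, p, Py - A[1], Py - B[1])
                    ez = _e_table(la, lb, p, Pz - A[2], Pz - B[2])
                    for ksh in range(nxs):
                        lc = xL[ksh]
                        C = xcenter[ksh]
                        ncc = ncart_l[lc]
                        for kp in range(xptr[ksh], xptr[ksh + 1]):
                            q = xexp[kp]
                            cc = xcoef[kp]
                            ec = _e_table(lc, 0, q, 0.0, 0.0)
                            alpha = p * q / (p + q)
                            pre = (kab * ca * cb * cc * 2.0 * math.pi ** 2.5
                                   / (p * q * math.sqrt(p + q)))
                            R = _r_tensor(la + lb + lc, alpha,
                                          Px - C[0], Py - C[1], Pz - C[2])
                            for ka in range(nca):
                                lxa = comp_lx[la, ka]
                                lya = comp_ly[la, ka]
                                lza = comp_lz[la, ka]
                                for kb in range(ncb):
                                    lxb = comp_lx[lb, kb]
                                    lyb = comp_ly[lb, kb]
                                    lzb = comp_lz[lb, kb]
                                    for kc in range(ncc):
                                        lxc = comp_lx[lc, kc]
                                        lyc = comp_ly[lc, kc]
                                        lzc = comp_lz[lc, kc]
                                        s = 0.0
                                        for t in range(lxa + lxb + 1):
                                            for u in range(lya + lyb + 1):
                                                for v in range(lza + lzb + 1):
                                                    e1 = (ex[lxa, lxb, t]
                                                          * ey[lya, lyb, u]
                                                          * ez[lza, lzb, v])
                                                    if e1 == 0.0:
                                                        continue
                                                    for t2 in range(lxc + 1):
                                                        for u2 in range(lyc + 1):
                                                            for v2 in range(lzc + 1):
                                                                e2 = (ec[lxc, 0, t2]
                                                                      * ec[lyc, 0, u2]
                                                                      * ec[lzc, 0, v2])
                                                                if e2 == 0.0:
                                                                    continue
                                                                sgn = 1.0 if (t2 + u2 + v2) % 2 == 0 else -1.0
                                                                s += e1 * e2 * sgn * R[t + t2, u + u2, v + v2]
                                        val = pre * s
                                        out[sh_off[ish] + ka,
                                            sh_off[jsh] + kb,
                                            xoff[ksh] + kc] += val
            # mirror lower triangle after all primitives accumulated
    for ish in range(nsh):
        for jsh in range(ish):
            oa, ob = sh_off[ish], sh_off[jsh]
            for ka in range(ncart_l[sh_L[ish]]):
                for kb in range(ncart_l[sh_L[jsh]]):
                    for x in range(out.shape[2]):
                        out[ob + kb, oa + ka, x] = out[oa + ka, ob + kb, x]


@njit(cache=False)
def _eri2c_kernel(xL, xcenter, xptr, xexp, xcoef, xoff,
                  comp_lx, comp_ly, comp_lz, ncart_l, out):
    nxs = len(xL)
    for ish in range(nxs):
        la = xL[ish]
        A = xcenter[ish]
        nca = ncart_l[la]
        for jsh in range(ish + 1):
            lb = xL[jsh]
            B = xcenter[jsh]
            ncb = ncart_l[lb]
            for ip in range(xptr[ish], xptr[ish + 1]):
                p = xexp[ip]
                ca = xcoef[ip]
                ea = _e_table(la, 0, p, 0.0, 0.0)
                for jp in range(xptr[jsh], xptr[jsh + 1]):
                    q = xexp[jp]
                    cb = xcoef[jp]
                    eb = _e_table(lb, 0, q, 0.0, 0.0)
                    alpha = p * q / (p + q)
                    pre = (ca * cb * 2.0 * math.pi ** 2.5
                           / (p * q * math.sqrt(p + q)))
                    R = _r_tensor(la + lb, alpha, A[0] - B[0],
                                  A[1] - B[1], A[2] - B[2])
                    for ka in range(nca):
                        lxa = comp_lx[la, ka]
                        lya = comp_ly[la, ka]
                        lza = comp_lz[la, ka]
                        for kb in range(ncb):
                            lxb = comp_lx[lb, kb]
                            lyb = comp_ly[lb, kb]
                            lzb = comp_lz[lb, kb]
                            s = 0.0
                            for t in range(lxa + 1):
                                for u in range(lya + 1):
                                    for v in range(lza + 1):
                                        e1 = (ea[lxa, 0, t] * ea[lya, 0, u]
                                              * ea[lza, 0, v])
                                        if e1 == 0.0:
                                            continue
                                        for t2 in range(lxb + 1):
                                            for u2 in range(lyb + 1):
                                                for v2 in range(lzb + 1):
                                                    e2 = (eb[lxb, 0, t2]
                                                          * eb[lyb, 0, u2]
                                                          * eb[lzb, 0, v2])
                                                    if e2 == 0.0:
                                                        continue
                                                    sgn = 1.0 if (t2 + u2 + v2) % 2 == 0 else -1.0
                                                    s += e1 * e2 * sgn * R[t + t2, u + u2, v + v2]
                            val = pre * s
                            out[xoff[ish] + ka, xoff[jsh] + kb] += val
    for i in range(out.shape[0]):
        for j in range(i):
            out[j, i] = out[i, j]


# -------------------------------------------------------------- components

def _comp_tables():
    lx = np.zeros((_LMAX + 1, (_LMAX + 1) * (_LMAX + 2) // 2), np.int64)
    ly = np.zeros_like(lx)
    lz = np.zeros_like(lx)
    nc = np.zeros(_LMAX + 1, np.int64)
    for L in range(_LMAX + 1):
        comps = _cart_components(L)
        nc[L] = len(comps)
        for k, (a, b, c) in enumerate(comps):
            lx[L, k], ly[L, k], lz[L, k] = a, b, c
    return lx, ly, lz, nc


_COMP_LX, _COMP_LY, _COMP_LZ, _NCART = _comp_tables()


def _shell_arrays(basis: AOBasis):
    return (basis.sh_L, basis.sh_center, basis.sh_ptr,
            basis.prim_exp, basis.prim_coef, basis.sh_off)


# ------------------------------------------------------- one-electron ints

def _s1d(la, lb, p, XPA, XPB):
    e = _e_table(la, lb, p, XPA, XPB)
    return e[:, :, 0] * math.sqrt(math.pi / p)


def _moment_1d(la, lb, emax, p, XPA, XPB, XPC):
    """<i|(x-C)^e|j> for i<=la, j<=lb, e<=emax via Hermite moments.

    Uses M_t^e = t*M_{t-1}^{e-1} + X_PC*M_t^{e-1} + M_{t+1}^{e-1}/(2p),
    with M_t^0 = delta_t0 * sqrt(pi/p).
    """
    e = _e_table(la, lb, p, XPA, XPB)
    tdim = la + lb + emax + 2
    m = np.zeros((tdim + 1, emax + 1))
    m[0, 0] = math.sqrt(math.pi / p)
    for order in range(1, emax + 1):
        for t in range(tdim):
            v = XPC * m[t, order - 1] + 0.5 / p * m[t + 1, order - 1]
            if t > 0:
                v += t * m[t - 1, order - 1]
            m[t, order] = v
    out = np.zeros((la + 1, lb + 1, emax + 1))
    for i in range(la + 1):
        for j in range(lb + 1):
            for order in range(emax + 1):
                s = 0.0
                for t in range(i + j + 1):
                    s += e[i, j, t] * m[t, order]
                out[i, j, order] = s
    return out


def _kin_1d(la, lb, p, b, XPA, XPB):
    """1D kinetic-energy integrals from overlaps with shifted momenta."""
    e = _e_table(la, lb + 2, p, XPA, XPB)
    s = e[:, :, 0] * math.sqrt(math.pi / p)
    t = np.zeros((la + 1, lb + 1))
    for i in range(la + 1):
        for j in range(lb + 1):
            v = -2.0 * b * b * s[i, j + 2] + b * (2 * j + 1) * s[i, j]
            if j >= 2:
                v -= 0.5 * j * (j - 1) * s[i, j - 2]
            t[i, j] = v
    return t


def _pair_loop_1e(basis: AOBasis, blockfun):
    """Drive a symmetric one-electron integral over shell pairs."""
    none = None
    for ish, sha in enumerate(basis.shells):
        for jsh in range(ish + 1):
            shb = basis.shells[jsh]
            yield ish, jsh, sha, shb


def overlap(basis: AOBasis) -> np.ndarray:
    S = np.zeros((basis.nao, basis.nao))
    for ish, jsh, sha, shb in _pair_loop_1e(basis, None):
        la, lb = sha.L, shb.L
        A, B = sha.center, shb.center
        block = np.zeros((len(_cart_components(la)), len(_cart_components(lb))))
        ab2 = float(np.dot(A - B, A - B))
        for a, ca in zip(sha.exps, sha.coefs):
            for b, cb in zip(shb.exps, shb.coefs):
                p = a + b
                kab = math.exp(-a * b / p * ab2)
                P = (a * A + b * B) / p
                sx = _s1d(la, lb, p, P[0] - A[0], P[0] - B[0])
                sy = _s1d(la, lb, p, P[1] - A[1], P[1] - B[1])
                sz = _s1d(la, lb, p, P[2] - A[2], P[2] - B[2])
                for ka, (lxa, lya, lza) in enumerate(_cart_components(la)):
                    for kb, (lxb, lyb, lzb) in enumerate(_cart_components(lb)):
                        block[ka, kb] += (ca * cb * kab * sx[lxa, lxb]
                                          * sy[lya, lyb] * sz[lza, lzb])
        _scatter(S, basis, ish, jsh, block)
    return _apply_comp_fac(S, basis)


def kinetic(basis: AOBasis) -> np.ndarray:
    T = np.zeros((basis.nao, basis.nao))
    for ish, jsh, sha, shb in _pair_loop_1e(basis, None):
        la, lb = sha.L, shb.L
        A, B = sha.center, shb.center
        block = np.zeros((len(_cart_components(la)), len(_cart_components(lb))))
        ab2 = float(np.dot(A - B, A - B))
        for a, ca in zip(sha.exps, sha.coefs):
            for b, cb in zip(shb.exps, shb.coefs):
                p = a + b
                kab = math.exp(-a * b / p * ab2)
                P = (a * A + b * B) / p
                sx = _s1d(la, lb, p, P[0] - A[0], P[0] - B[0])
                sy = _s1d(la, lb, p, P[1] - A[1], P[1] - B[1])
                sz = _s1d(la, lb, p, P[2] - A[2], P[2] - B[2])
                tx = _kin_1d(la, lb, p, b, P[0] - A[0], P[0] - B[0])
                ty = _kin_1d(la, lb, p, b, P[1] - A[1], P[1] - B[1])
                tz = _kin_1d(la, lb, p, b, P[2] - A[2], P[2] - B[2])
                for ka, (lxa, lya, lza) in enumerate(_cart_components(la)):
                    for kb, (lxb, lyb, lzb) in enumerate(_cart_components(lb)):
                        block[ka, kb] += ca * cb * kab * (
                            tx[lxa, lxb] * sy[lya, lyb] * sz[lza, lzb]
                            + sx[lxa, lxb] * ty[lya, lyb] * sz[lza, lzb]
                            + sx[lxa, lxb] * sy[lya, lyb] * tz[lza, lzb])
        _scatter(T, basis, ish, jsh, block)
    return _apply_comp_fac(T, basis)


def multipole(basis: AOBasis, order: int = 2,
              center=(0.0, 0.0, 0.0)) -> dict:
    """Cartesian moment integrals about `center`.

    Returns a dict mapping component tuples (ex, ey, ez) with
    1 <= ex+ey+ez <= order to (nao, nao) arrays of <mu|prod (r-C)^e|nu>.
    """
    C = np.asarray(center, float)
    keys = [k for L in range(1, order + 1) for k in _cart_components(L)]
    out = {k: np.zeros((basis.nao, basis.nao)) for k in keys}
    for ish, jsh, sha, shb in _pair_loop_1e(basis, None):
        la, lb = sha.L, shb.L
        A, B = sha.center, shb.center
        nca, ncb = len(_cart_components(la)), len(_cart_components(lb))
        blocks = {k: np.zeros((nca, ncb)) for k in keys}
        ab2 = float(np.dot(A - B, A - B))
        for a, ca in zip(sha.exps, sha.coefs):
            for b, cb in zip(shb.exps, shb.coefs):
                p = a + b
                kab = math.exp(-a * b / p * ab2)
                P = (a * A + b * B) / p
                mx = _moment_1d(la, lb, order, p, P[0] - A[0], P[0] - B[0],
                                P[0] - C[0])
                my = _moment_1d(la, lb, order, p, P[1] - A[1], P[1] - B[1],
                                P[1] - C[1])
                mz = _moment_1d(la, lb, order, p, P[2] - A[2], P[2] - B[2],
                                P[2] - C[2])
                for ka, (lxa, lya, lza) in enumerate(_cart_components(la)):
                    for kb, (lxb, lyb, lzb) in enumerate(_cart_components(lb)):
                        w = ca * cb * kab
                        for (ex, ey, ez) in keys:
                            blocks[(ex, ey, ez)][ka, kb] += w * (
                                mx[lxa, lxb, ex] * my[lya, lyb, ey]
                                * mz[lza, lzb, ez])
        for k in keys:
            _scatter(out[k], basis, ish, jsh, blocks[k])
    return {k: _apply_comp_fac(v, basis) for k, v in out.items()}


def nuclear_attraction(basis: AOBasis) -> np.ndarray:
    V = np.zeros((basis.nao, basis.nao))
    _nuclear_kernel(*_shell_arrays(basis), _COMP_LX, _COMP_LY, _COMP_LZ,
                    _NCART, basis.mol.charges, basis.mol.coords, V)
    return _apply_comp_fac(V, basis)


def eri_3c(basis: AOBasis, aux: AOBasis) -> np.ndarray:
    """Three-center Coulomb integrals (mu nu | X), shape (nao, nao, naux)."""
    out = np.zeros((basis.nao, basis.nao, aux.nao))
    _eri3c_kernel(*_shell_arrays(basis), aux.sh_L, aux.sh_center, aux.sh_ptr,
                  aux.prim_exp, aux.prim_coef, aux.sh_off,
                  _COMP_LX, _COMP_LY, _COMP_LZ, _NCART, out)
    out *= basis.comp_fac[:, None, None]
    out *= basis.comp_fac[None, :, None]
    out *= aux.comp_fac[None, None, :]
    return out


def eri_2c(aux: AOBasis) -> np.ndarray:
    """Two-center Coulomb metric (X|Y)."""
    out = np.zeros((aux.nao, aux.nao))
    _eri2c_kernel(aux.sh_L, aux.sh_center, aux.sh_ptr, aux.prim_exp,
                  aux.prim_coef, aux.sh_off,
                  _COMP_LX, _COMP_LY, _COMP_LZ, _NCART, out)
    return _apply_comp_fac(out, aux)


def _scatter(M, basis, ish, jsh, block):
    oa, ob = basis.shell_offsets[ish], basis.shell_offsets[jsh]
    na, nb = block.shape
    M[oa:oa + na, ob:ob + nb] += block
    if ish != jsh:
        M[ob:ob + nb, oa:oa + na] += block.T


def _apply_comp_fac(M, basis, basis2=None):
    b2 = basis if basis2 is None else basis2
    return M * basis.comp_fac[:, None] * b2.comp_fac[None, :]
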