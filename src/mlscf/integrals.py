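"""Molecular integrals over contracted cartesian Gaussians (s and p shells).

McMurchie–Davidson scheme: Hermite expansion coefficients for overlap-like
integrals, Boys-function-based Hermite Coulomb tensors for nuclear-attraction,
point-charge and electron-repulsion integrals.  The two-electron tensor and
the batched point-charge potential matrices are numba-compiled; one-shot
one-electron integrals reuse the same kernels.

The engine is deliberately in-core: the full (nao, nao, nao, nao) repulsion
tensor is stored, which caps practical system sizes at roughly 100 AOs —
ample for the droplet-scale systems this package targets.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .basis import BasisSet, CART_COMPONENTS

# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

_CART = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=np.int64
)
_CART_OFF = np.array([0, 1], dtype=np.int64)  # row offset into _CART per l


@njit(cache=True)
def _boys(T, mmax, out):
    """Boys functions F_0..F_mmax(T) into out (len >= mmax+1)."""
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1) - T / (2 * m + 3)
        return
    if T < 35.0:
        # series for F_mmax, then stable downward recursion
        denom = 2.0 * mmax + 1.0
        term = 1.0 / denom
        s = term
        k = 0
        while term > 1e-17 * s and k < 300:
            k += 1
            term *= 2.0 * T / (2.0 * mmax + 2.0 * k + 1.0)
            s += term
        emt = np.exp(-T)
        out[mmax] = emt * s
        for m in range(mmax - 1, -1, -1):
            out[m] = (2.0 * T * out[m + 1] + emt) / (2 * m + 1)
    else:
        emt = np.exp(-T)
        out[0] = 0.5 * np.sqrt(np.pi / T)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - emt) / (2.0 * T)


@njit(cache=True)
def _e_coeffs(la, lb, A, B, a, b, E):
    """Hermite expansion coefficients E[d, i, j, t] for one primitive pair.

    Includes the gaussian product prefactor exp(-mu*AB_d^2) per dimension.
    Supports i <= la, j <= lb (caller sizes: la+1, lb+1, la+lb+1 in t).
    """
    p = a + b
    mu = a * b / p
    o2p = 1.0 / (2.0 * p)
    for d in range(3):
        AB = A[d] - B[d]
        PA = -b / p * AB
        PB = a / p * AB
        E[d, :, :, :] = 0.0
        E[d, 0, 0, 0] = np.exp(-mu * AB * AB)
        for i in range(1, la + 1):
            for t in range(i + 1):
                v = PA * E[d, i - 1, 0, t]
                if t > 0:
                    v += o2p * E[d, i - 1, 0, t - 1]
                if t + 1 <= i - 1:
                    v += (t + 1) * E[d, i - 1, 0, t + 1]
                E[d, i, 0, t] = v
        for j in range(1, lb + 1):
            for i in range(la + 1):
                for t in range(i + j + 1):
                    v = PB * E[d, i, j - 1, t]
                    if t > 0:
                        v += o2p * E[d, i, j - 1, t - 1]
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[d, i, j - 1, t + 1]
                    E[d, i, j, t] = v


@njit(cache=True)
def _r_tensor(ntot, alpha, X, Y, Z, Fm, R):
    """Hermite Coulomb integrals R_{tuv} (n=0) for t+u+v <= ntot.

    R is a scratch array of shape (ntot+1, ntot+1, ntot+1, ntot+1) indexed
    [n, t, u, v]; the n=0 slice holds the result.
    """
    for n in range(ntot, -1, -1):
        m2a = (-2.0 * alpha) ** n
        for t in range(ntot - n + 1):
            for u in range(ntot - n - t + 1):
                for v in range(ntot - n - t - u + 1):
                    if t == 0 and u == 0 and v == 0:
                        R[n, 0, 0, 0] = m2a * Fm[n]
                    elif t > 0:
                        val = X * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                        R[n, t, u, v] = val
                    elif u > 0:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                        R[n, t, u, v] = val
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                        R[n, t, u, v] = val


@njit(cache=True)
def _overlap_kinetic(l_arr, np_arr, exps, coefs, cen, off, nao):
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    nsh = len(l_arr)
    E = np.zeros((3, 4, 6, 10))
    sqpi = np.sqrt(np.pi)
    for ish in range(nsh):
        la = l_arr[ish]
        A = cen[ish]
        for jsh in range(ish + 1):
            lb = l_arr[jsh]
            B = cen[jsh]
            nca = (la + 1) * (la + 2) // 2
            ncb = (lb + 1) * (lb + 2) // 2
            sblk = np.zeros((nca, ncb))
            tblk = np.zeros((nca, ncb))
            for ip in range(np_arr[ish]):
                a = exps[ish, ip]
                ca = coefs[ish, ip]
                for jp in range(np_arr[jsh]):
                    b = exps[jsh, jp]
                    cb = coefs[jsh, jp]
                    p = a + b
                    _e_coeffs(la, lb + 2, A, B, a, b, E)
                    fac = ca * cb * (sqpi / np.sqrt(p)) ** 3
                    for ia in range(nca):
                        li = _CART[_CART_OFF[la] + ia]
                        for jb in range(ncb):
                            lj = _CART[_CART_OFF[lb] + jb]
                            s1 = np.zeros(3)
                            t1 = np.zeros(3)
                            for d in range(3):
                                i = li[d]
                                j = lj[d]
                                s1[d] = E[d, i, j, 0]
                                tv = b * (2 * j + 1) * E[d, i, j, 0]
                                tv -= 2.0 * b * b * E[d, i, j + 2, 0]
                                if j >= 2:
                                    tv -= 0.5 * j * (j - 1) * E[d, i, j - 2, 0]
                                t1[d] = tv
                            sblk[ia, jb] += fac * s1[0] * s1[1] * s1[2]
                            tblk[ia, jb] += fac * (
                                t1[0] * s1[1] * s1[2]
                                + s1[0] * t1[1] * s1[2]
                                + s1[0] * s1[1] * t1[2]
                            )
            for ia in range(nca):
                for jb in range(ncb):
                    mu = off[ish] + ia
                    nu = off[jsh] + jb
                    S[mu, nu] = sblk[ia, jb]
                    S[nu, mu] = sblk[ia, jb]
                    T[mu, nu] = tblk[ia, jb]
                    T[nu, mu] = tblk[ia, jb]
    return S, T


@njit(cache=True)
def _point_potential(l_arr, np_arr, exps, coefs, cen, off, nao, points):
    """out[k] = matrix of attraction integrals <mu| 1/|r - C_k| |nu> (positive)."""
    npts = points.shape[0]
    out = np.zeros((npts, nao, nao))
    nsh = len(l_arr)
    E = np.zeros((3, 4, 6, 10))
    Fm = np.zeros(12)
    R = np.zeros((6, 6, 6, 6))
    for ish in range(nsh):
        la = l_arr[ish]
        A = cen[ish]
        for jsh in range(ish + 1):
            lb = l_arr[jsh]
            B = cen[jsh]
            nca = (la + 1) * (la + 2) // 2
            ncb = (lb + 1) * (lb + 2) // 2
            ntot = la + lb
            for ip in range(np_arr[ish]):
                a = exps[ish, ip]
                ca = coefs[ish, ip]
                for jp in range(np_arr[jsh]):
                    b = exps[jsh, jp]
                    cb = coefs[jsh, jp]
                    p = a + b
                    P0 = (a * A[0] + b * B[0]) / p
                    P1 = (a * A[1] + b * B[1]) / p
                    P2 = (a * A[2] + b * B[2]) / p
                    _e_coeffs(la, lb, A, B, a, b, E)
                    fac = ca * cb * 2.0 * np.pi / p
                    for k in range(npts):
                        X = P0 - points[k, 0]
                        Y = P1 - points[k, 1]
                        Z = P2 - points[k, 2]
                        Tb = p * (X * X + Y * Y + Z * Z)
                        _boys(Tb, ntot, Fm)
                        _r_tensor(ntot, p, X, Y, Z, Fm, R)
                        for ia in range(nca):
                            li = _CART[_CART_OFF[la] + ia]
                            for jb in range(ncb):
                                lj = _CART[_CART_OFF[lb] + jb]
                                val = 0.0
                                for t in range(li[0] + lj[0] + 1):
                                    Ex = E[0, li[0], lj[0], t]
                                    for u in range(li[1] + lj[1] + 1):
                                        Ey = E[1, li[1], lj[1], u]
                                        for v in range(li[2] + lj[2] + 1):
                                            val += (
                                                Ex * Ey
                                                * E[2, li[2], lj[2], v]
                                                * R[0, t, u, v]
                                            )
                                out[k, off[ish] + ia, off[jsh] + jb] += fac * val
    for k in range(npts):
        for mu in range(nao):
            for nu in range(mu):
                out[k, nu, mu] = out[k, mu, nu]
    return out


@njit(cache=True)
def _eri_tensor(l_arr, np_arr, exps, coefs, cen, off, nao, schwarz, tol):
    nsh = len(l_arr)
    out = np.zeros((nao, nao, nao, nao))
    Eab = np.zeros((3, 4, 6, 10))
    Ecd = np.zeros((3, 4, 6, 10))
    Fm = np.zeros(12)
    R = np.zeros((6, 6, 6, 6))
    pi52 = 2.0 * np.pi ** 2.5
    for ash in range(nsh):
        la = l_arr[ash]
        A = cen[ash]
        nca = (la + 1) * (la + 2) // 2
        for bsh in range(ash + 1):
            lb = l_arr[bsh]
            B = cen[bsh]
            ncb = (lb + 1) * (lb + 2) // 2
            pair_ab = ash * (ash + 1) // 2 + bsh
            for csh in range(ash + 1):
                lc = l_arr[csh]
                C = cen[csh]
                ncc = (lc + 1) * (lc + 2) // 2
                for dsh in range(csh + 1):
                    pair_cd = csh * (csh + 1) // 2 + dsh
                    if pair_cd > pair_ab:
                        continue
                    if schwarz[ash, bsh] * schwarz[csh, dsh] < tol:
                        continue
                    ld = l_arr[dsh]
                    D = cen[dsh]
                    ncd = (ld + 1) * (ld + 2) // 2
                    ntot = la + lb + lc + ld
                    blk = np.zeros((nca, ncb, ncc, ncd))
                    for ip in range(np_arr[ash]):
                        a = exps[ash, ip]
                        ca = coefs[ash, ip]
                        for jp in range(np_arr[bsh]):
                            b = exps[bsh, jp]
                            cb = coefs[bsh, jp]
                            p = a + b
                            Px = (a * A[0] + b * B[0]) / p
                            Py = (a * A[1] + b * B[1]) / p
                            Pz = (a * A[2] + b * B[2]) / p
                            _e_coeffs(la, lb, A, B, a, b, Eab)
                            kab = Eab[0, 0, 0, 0] * Eab[1, 0, 0, 0] * Eab[2, 0, 0, 0]
                            # cheap primitive bound
                            if abs(ca * cb) * kab < 1e-16:
                                continue
                            for kp in range(np_arr[csh]):
                                c = exps[csh, kp]
                                cc = coefs[csh, kp]
                                for lp in range(np_arr[dsh]):
                                    d = exps[dsh, lp]
                                    cd = coefs[dsh, lp]
                                    q = c + d
                                    Qx = (c * C[0] + d * D[0]) / q
                                    Qy = (c * C[1] + d * D[1]) / q
                                    Qz = (c * C[2] + d * D[2]) / q
                                    _e_coeffs(lc, ld, C, D, c, d, Ecd)
                                    kcd = (
                                        Ecd[0, 0, 0, 0]
                                        * Ecd[1, 0, 0, 0]
                                        * Ecd[2, 0, 0, 0]
                                    )
                                    pref = pi52 / (p * q * np.sqrt(p + q))
                                    if (
                                        abs(ca * cb * cc * cd) * kab * kcd * pref
                                        < 1e-16
                                    ):
                                        continue
                                    alpha = p * q / (p + q)
                                    X = Px - Qx
                                    Y = Py - Qy
                                    Z = Pz - Qz
                                    Tb = alpha * (X * X + Y * Y + Z * Z)
                                    _boys(Tb, ntot, Fm)
                                    _r_tensor(ntot, alpha, X, Y, Z, Fm, R)
                                    cfac = ca * cb * cc * cd * pref
                                    for ia in range(nca):
                                        li = _CART[_CART_OFF[la] + ia]
                                        for jb in range(ncb):
                                            lj = _CART[_CART_OFF[lb] + jb]
                                            tx = li[0] + lj[0]
                                            ty = li[1] + lj[1]
                                            tz = li[2] + lj[2]
                                            for kc in range(ncc):
                                                lk = _CART[_CART_OFF[lc] + kc]
                                                for ldx in range(ncd):
                                                    ll = _CART[_CART_OFF[ld] + ldx]
                                                    sx = lk[0] + ll[0]
                                                    sy = lk[1] + ll[1]
                                                    sz = lk[2] + ll[2]
                                                    val = 0.0
                                                    for t in range(tx + 1):
                                                        e1 = Eab[0, li[0], lj[0], t]
                                                        for u in range(ty + 1):
                                                            e2 = e1 * Eab[1, li[1], lj[1], u]
                                                            for v in range(tz + 1):
                                                                e3 = e2 * Eab[2, li[2], lj[2], v]
                                                                if e3 == 0.0:
                                                                    continue
                                                                acc = 0.0
                                                                for tt in range(sx + 1):
                                                                    f1 = Ecd[0, lk[0], ll[0], tt]
                                                                    for uu in range(sy + 1):
                                                                        f2 = f1 * Ecd[1, lk[1], ll[1], uu]
                                                                        for vv in range(sz + 1):
                                                                            f3 = f2 * Ecd[2, lk[2], ll[2], vv]
                                                                            if f3 == 0.0:
                                                                                continue
                                                                            sgn = 1.0
                                                                            if (tt + uu + vv) % 2 == 1:
                                                                                sgn = -1.0
                                                                            acc += sgn * f3 * R[0, t + tt, u + uu, v + vv]
                                                                val += e3 * acc
                                                    blk[ia, jb, kc, ldx] += cfac * val
                    # scatter with 8-fold symmetry
                    for ia in range(nca):
                        mu = off[ash] + ia
                        for jb in range(ncb):
                            nu = off[bsh] + jb
                            for kc in range(ncc):
                                lam = off[csh] + kc
                                for ldx in range(ncd):
                                    sig = off[dsh] + ldx
                                    v = blk[ia, jb, kc, ldx]
                                    out[mu, nu, lam, sig] = v
                                    out[nu, mu, lam, sig] = v
                                    out[mu, nu, sig, lam] = v
                                    out[nu, mu, sig, lam] = v
                                    out[lam, sig, mu, nu] = v
                                    out[sig, lam, mu, nu] = v
                                    out[lam, sig, nu, mu] = v
                                    out[sig, lam, nu, mu] = v
    return out


@njit(cache=True)
def _schwarz_bounds(l_arr, np_arr, exps, coefs, cen):
    """sqrt(max_component (ab|ab)) per shell pair, for Cauchy-Schwarz screening."""
    nsh = len(l_arr)
    out = np.zeros((nsh, nsh))
    Eab = np.zeros((3, 4, 6, 10))
    Ecd = np.zeros((3, 4, 6, 10))
    Fm = np.zeros(12)
    R = np.zeros((6, 6, 6, 6))
    pi52 = 2.0 * np.pi ** 2.5
    for ash in range(nsh):
        la = l_arr[ash]
        A = cen[ash]
        nca = (la + 1) * (la + 2) // 2
        for bsh in range(ash + 1):
            lb = l_arr[bsh]
            B = cen[bsh]
            ncb = (lb + 1) * (lb + 2) // 2
            ntot = 2 * (la + lb)
            diag = np.zeros((nca, ncb))
            for ip in range(np_arr[ash]):
                a = exps[ash, ip]
                ca = coefs[ash, ip]
                for jp in range(np_arr[bsh]):
                    b = exps[bsh, jp]
                    cb = coefs[bsh, jp]
                    p = a + b
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    _e_coeffs(la, lb, A, B, a, b, Eab)
                    for kp in range(np_arr[ash]):
                        c = exps[ash, kp]
                        cc = coefs[ash, kp]
                        for lp in range(np_arr[bsh]):
                            d = exps[bsh, lp]
                            cd = coefs[bsh, lp]
                            q = c + d
                            Qx = (c * A[0] + d * B[0]) / q
                            Qy = (c * A[1] + d * B[1]) / q
                            Qz = (c * A[2] + d * B[2]) / q
                            _e_coeffs(la, lb, A, B, c, d, Ecd)
                            alpha = p * q / (p + q)
                            X = Px - Qx
                            Y = Py - Qy
                            Z = Pz - Qz
                            Tb = alpha * (X * X + Y * Y + Z * Z)
                            _boys(Tb, ntot, Fm)
                            _r_tensor(ntot, alpha, X, Y, Z, Fm, R)
                            cfac = (
                                ca * cb * cc * cd * pi52
                                / (p * q * np.sqrt(p + q))
                            )
                            for ia in range(nca):
                                li = _CART[_CART_OFF[la] + ia]
                                for jb in range(ncb):
                                    lj = _CART[_CART_OFF[lb] + jb]
                                    tx = li[0] + lj[0]
                                    ty = li[1] + lj[1]
                                    tz = li[2] + lj[2]
                                    sval = 0.0
                                    for t in range(tx + 1):
                                        e1 = Eab[0, li[0], lj[0], t]
                                        for u in range(ty + 1):
                                            e2 = e1 * Eab[1, li[1], lj[1], u]
                                            for v in range(tz + 1):
                                                e3 = e2 * Eab[2, li[2], lj[2], v]
                                                acc = 0.0
                                                for tt in range(tx + 1):
                                                    f1 = Ecd[0, li[0], lj[0], tt]
                                                    for uu in range(ty + 1):
                                                        f2 = f1 * Ecd[1, li[1], lj[1], uu]
                                                        for vv in range(tz + 1):
                                                            f3 = f2 * Ecd[2, li[2], lj[2], vv]
                                                            sgn = 1.0
                                                            if (tt + uu + vv) % 2 == 1:
                                                                sgn = -1.0
                                                            acc += sgn * f3 * R[0, t + tt, u + uu, v + vv]
                                                sval += e3 * acc
                                    diag[ia, jb] += cfac * sval
            mx = 0.0
            for ia in range(nca):
                for jb in range(ncb):
                    if abs(diag[ia, jb]) > mx:
                        mx = abs(diag[ia, jb])
            out[ash, bsh] = np.sqrt(mx)
            out[bsh, ash] = out[ash, bsh]
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def overlap_kinetic(basis: BasisSet):
    """Overlap and kinetic-energy matrices (a.u.)."""
    S, T = _overlap_kinetic(*basis.packed(), basis.nao)
    return S, T


def point_charge_integrals(basis: BasisSet, points_bohr: np.ndarray):
    """Attraction-integral matrices <mu|1/|r-C_k||nu> for each point (positive)."""
    pts = np.ascontiguousarray(np.atleast_2d(points_bohr), dtype=float)
    return _point_potential(*basis.packed(), basis.nao, pts)


def nuclear_attraction(basis: BasisSet, coords_bohr: np.ndarray,
                       charges: np.ndarray):
    """Nuclear-attraction matrix V = -sum_K Z_K <mu|1/|r-R_K||nu>."""
    mats = point_charge_integrals(basis, coords_bohr)
    return -np.einsum("k,kmn->mn", np.asarray(charges, float), mats)


def eri_tensor(basis: BasisSet, screen_tol: float = 1e-12):
    """Full two-electron repulsion tensor (mu nu | lam sig), chemists' notation."""
    packed = basis.packed()
    schwarz = _schwarz_bounds(*packed[:5])
    return _eri_tensor(*packed, basis.nao, schwarz, screen_tol)


def ao_values(basis: BasisSet, points_bohr: np.ndarray, deriv: int = 0):
    """AO values (and optionally cartesian gradients) at points.

    Returns (npts, nao) for deriv=0, else (4, npts, nao) stacked as
    [value, d/dx, d/dy, d/dz].
    """
    pts = np.atleast_2d(np.asarray(points_bohr, float))
    npts = pts.shape[0]
    nao = basis.nao
    if deriv == 0:
        out = np.zeros((npts, nao))
    else:
        out = np.zeros((4, npts, nao))
    for sh in basis.shells:
        d = pts - sh.center[None, :]
        r2 = np.einsum("pi,pi->p", d, d)
        expv = np.exp(-np.outer(r2, sh.exps))          # (npts, nprim)
        rad = expv @ sh.coefs
        comps = CART_COMPONENTS[sh.l]
        if deriv == 0:
            for c, (lx, ly, lz) in enumerate(comps):
                mono = d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz
                out[:, sh.ao_start + c] = mono * rad
        else:
            radd = expv @ (sh.coefs * (-2.0 * sh.exps))  # d rad / d(r^2)
            for c, (lx, ly, lz) in enumerate(comps):
                ls = (lx, ly, lz)
                mono = d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz
                out[0, :, sh.ao_start + c] = mono * rad
                for ax in range(3):
                    g = mono * d[:, ax] * radd
                    if ls[ax] > 0:
                        dm = np.ones(npts)
                        for ax2 in range(3):
                            ll = ls[ax2] - 1 if ax2 == ax else ls[ax2]
                            if ll > 0:
                                dm = dm * d[:, ax2] ** ll
                        g = g + ls[ax] * dm * rad
                    out[ax + 1, :, sh.ao_start + c] = g
    return out


def nuclear_repulsion(coords_bohr: np.ndarray, charges: np.ndarray) -> float:
    """Point-charge repulsion energy of the nuclei (a.u.)."""
    e = 0.0
    n = len(charges)
    for i in range(n):
        for j in range(i):
            e += charges[i] * charges[j] / np.linalg.norm(
                coords_bohr[i] - coords_bohr[j]
            )
    return float(e)
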