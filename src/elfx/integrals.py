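"""Gaussian one- and two-electron integrals (McMurchie–Davidson scheme).

Primitive Cartesian Gaussians g(r) = N x^l y^m z^n exp(-a r^2) are
combined through Hermite expansion coefficients; nuclear-attraction and
repulsion integrals use the Hermite Coulomb recursion on top of the Boys
function.  The hot loops are numba-compiled; the public entry point
builds full S, T, V and the 4-index electron-repulsion tensor for a
shell list.

Supports arbitrary angular momentum in principle; the built-in SCF
backend only exercises s and p shells.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["build_integrals", "boys"]

_SQRT_PI = math.sqrt(math.pi)


@njit(cache=True)
def _boys_array(m_max, x, out):
    """Fill out[0..m_max] with Boys functions F_m(x)."""
    if x < 1e-14:
        for m in range(m_max + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if x > 38.0:
        # asymptotic F_0, upward recursion (e^-x negligible)
        out[0] = 0.5 * math.sqrt(math.pi / x)
        for m in range(m_max):
            out[m + 1] = (2.0 * m + 1.0) * out[m] / (2.0 * x)
        return
    # series for F_{m_max}, then stable downward recursion
    expx = math.exp(-x)
    term = 1.0 / (2.0 * m_max + 1.0)
    total = term
    k = 1
    while True:
        term *= 2.0 * x / (2.0 * m_max + 2.0 * k + 1.0)
        total += term
        if term < 1e-17 * total or k > 250:
            break
        k += 1
    out[m_max] = total * expx
    for m in range(m_max, 0, -1):
        out[m - 1] = (2.0 * x * out[m] + expx) / (2.0 * m - 1.0)


def boys(m, x):
    """Boys function F_m(x) (scalar convenience wrapper)."""
    out = np.empty(m + 1)
    _boys_array(m, float(x), out)
    return out[m]


@njit(cache=True)
def _hermite_E_ws(i, j, a, b, AB, out, tab):
    """Hermite expansion coefficients E_t^{ij} into a caller workspace."""
    p = a + b
    mu = a * b / p
    n = i + j
    tab[: i + 1, : j + 1, : n + 2] = 0.0
    tab[0, 0, 0] = math.exp(-mu * AB * AB)
    XPA = -b * AB / p  # P - A with A at origin convention: AB = A - B
    XPB = a * AB / p   # P - B
    for ii in range(1, i + 1):
        for t in range(ii + 1):
            v = XPA * tab[ii - 1, 0, t]
            if t > 0:
                v += tab[ii - 1, 0, t - 1] / (2.0 * p)
            v += (t + 1) * tab[ii - 1, 0, t + 1]
            tab[ii, 0, t] = v
    for jj in range(1, j + 1):
        for ii in range(i + 1):
            for t in range(ii + jj + 1):
                v = XPB * tab[ii, jj - 1, t]
                if t > 0:
                    v += tab[ii, jj - 1, t - 1] / (2.0 * p)
                v += (t + 1) * tab[ii, jj - 1, t + 1]
                tab[ii, jj, t] = v
    for t in range(n + 1):
        out[t] = tab[i, j, t]


@njit(cache=True)
def _hermite_E(i, j, a, b, AB, out):
    """Hermite expansion coefficients E_t^{ij}, t = 0..i+j, 1D."""
    tab = np.zeros((i + 1, j + 1, i + j + 2))
    _hermite_E_ws(i, j, a, b, AB, out, tab)


@njit(cache=True)
def _overlap_1d(i, j, a, b, AB):
    p = a + b
    tmp = np.zeros(i + j + 2)
    _hermite_E(i, j, a, b, AB, tmp)
    return tmp[0] * math.sqrt(math.pi / p)


@njit(cache=True)
def _overlap_prim(la, ma, na, lb, mb, nb, a, b, A, B):
    sx = _overlap_1d(la, lb, a, b, A[0] - B[0])
    sy = _overlap_1d(ma, mb, a, b, A[1] - B[1])
    sz = _overlap_1d(na, nb, a, b, A[2] - B[2])
    return sx * sy * sz


@njit(cache=True)
def _kinetic_prim(la, ma, na, lb, mb, nb, a, b, A, B):
    # 1D kinetic factor K_ij = -2b^2 S_{i,j+2} + b(2j+1) S_{ij}
    #                          - j(j-1)/2 S_{i,j-2}
    def k1d(i, j, ax, bx, AB):
        v = -2.0 * bx * bx * _overlap_1d(i, j + 2, ax, bx, AB)
        v += bx * (2.0 * j + 1.0) * _overlap_1d(i, j, ax, bx, AB)
        if j >= 2:
            v -= 0.5 * j * (j - 1.0) * _overlap_1d(i, j - 2, ax, bx, AB)
        return v

    sx = _overlap_1d(la, lb, a, b, A[0] - B[0])
    sy = _overlap_1d(ma, mb, a, b, A[1] - B[1])
    sz = _overlap_1d(na, nb, a, b, A[2] - B[2])
    kx = k1d(la, lb, a, b, A[0] - B[0])
    ky = k1d(ma, mb, a, b, A[1] - B[1])
    kz = k1d(na, nb, a, b, A[2] - B[2])
    return kx * sy * sz + sx * ky * sz + sx * sy * kz


@njit(cache=True)
def _hermite_R_ws(tmax, umax, vmax, p, PC, full, boys_buf):
    """Hermite Coulomb integrals; results land in full[0, t, u, v]."""
    nmax = tmax + umax + vmax
    x = p * (PC[0] * PC[0] + PC[1] * PC[1] + PC[2] * PC[2])
    _boys_array(nmax, x, boys_buf)
    # R^n_{000} = (-2p)^n F_n(x)
    fac = 1.0
    for n in range(nmax + 1):
        full[n, 0, 0, 0] = fac * boys_buf[n]
        fac *= -2.0 * p
    for t in range(1, tmax + 1):
        for n in range(nmax - t + 1):
            v = PC[0] * full[n + 1, t - 1, 0, 0]
            if t > 1:
                v += (t - 1) * full[n + 1, t - 2, 0, 0]
            full[n, t, 0, 0] = v
    for u in range(1, umax + 1):
        for t in range(tmax + 1):
            for n in range(nmax - t - u + 1):
                v = PC[1] * full[n + 1, t, u - 1, 0]
                if u > 1:
                    v += (u - 1) * full[n + 1, t, u - 2, 0]
                full[n, t, u, 0] = v
    for v_ in range(1, vmax + 1):
        for u in range(umax + 1):
            for t in range(tmax + 1):
                for n in range(nmax - t - u - v_ + 1):
                    val = PC[2] * full[n + 1, t, u, v_ - 1]
                    if v_ > 1:
                        val += (v_ - 1) * full[n + 1, t, u, v_ - 2]
                    full[n, t, u, v_] = val


@njit(cache=True)
def _hermite_R(tmax, umax, vmax, p, PC, out):
    nmax = tmax + umax + vmax
    full = np.zeros((nmax + 1, tmax + 1, umax + 1, vmax + 1))
    boys_buf = np.empty(nmax + 1)
    _hermite_R_ws(tmax, umax, vmax, p, PC, full, boys_buf)
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v_ in range(vmax + 1):
                out[t, u, v_] = full[0, t, u, v_]


@njit(cache=True)
def _nuclear_prim(la, ma, na, lb, mb, nb, a, b, A, B, C):
    p = a + b
    P = (a * A + b * B) / p
    Ex = np.zeros(la + lb + 1)
    Ey = np.zeros(ma + mb + 1)
    Ez = np.zeros(na + nb + 1)
    _hermite_E(la, lb, a, b, A[0] - B[0], Ex)
    _hermite_E(ma, mb, a, b, A[1] - B[1], Ey)
    _hermite_E(na, nb, a, b, A[2] - B[2], Ez)
    R = np.zeros((la + lb + 1, ma + mb + 1, na + nb + 1))
    _hermite_R(la + lb, ma + mb, na + nb, p, P - C, R)
    total = 0.0
    for t in range(la + lb + 1):
        for u in range(ma + mb + 1):
            for v in range(na + nb + 1):
                total += Ex[t] * Ey[u] * Ez[v] * R[t, u, v]
    return 2.0 * math.pi / p * total


@njit(cache=True)
def _eri_prim_ws(la, ma, na, lb, mb, nb, lc, mc, nc, ld, md, nd,
                 a, b, c, d, A, B, C, D,
                 E1x, E1y, E1z, E2x, E2y, E2z, etab, rfull, boys_buf):
    p = a + b
    q = c + d
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    alpha = p * q / (p + q)
    _hermite_E_ws(la, lb, a, b, A[0] - B[0], E1x, etab)
    _hermite_E_ws(ma, mb, a, b, A[1] - B[1], E1y, etab)
    _hermite_E_ws(na, nb, a, b, A[2] - B[2], E1z, etab)
    _hermite_E_ws(lc, ld, c, d, C[0] - D[0], E2x, etab)
    _hermite_E_ws(mc, md, c, d, C[1] - D[1], E2y, etab)
    _hermite_E_ws(nc, nd, c, d, C[2] - D[2], E2z, etab)
    tmax = la + lb + lc + ld
    umax = ma + mb + mc + md
    vmax = na + nb + nc + nd
    _hermite_R_ws(tmax, umax, vmax, alpha, P - Q, rfull, boys_buf)
    total = 0.0
    for t in range(la + lb + 1):
        for u in range(ma + mb + 1):
            for v in range(na + nb + 1):
                e1 = E1x[t] * E1y[u] * E1z[v]
                if e1 == 0.0:
                    continue
                for tt in range(lc + ld + 1):
                    for uu in range(mc + md + 1):
                        for vv in range(nc + nd + 1):
                            e2 = E2x[tt] * E2y[uu] * E2z[vv]
                            if e2 == 0.0:
                                continue
                            sign = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                            total += e1 * e2 * sign \
                                * rfull[0, t + tt, u + uu, v + vv]
    pref = 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
    return pref * total


@njit(cache=True)
def _eri_prim(la, ma, na, lb, mb, nb, lc, mc, nc, ld, md, nd,
              a, b, c, d, A, B, C, D):
    L = la + ma + na + lb + mb + nb + lc + mc + nc + ld + md + nd
    E1x = np.zeros(2 * L + 1)
    E1y = np.zeros(2 * L + 1)
    E1z = np.zeros(2 * L + 1)
    E2x = np.zeros(2 * L + 1)
    E2y = np.zeros(2 * L + 1)
    E2z = np.zeros(2 * L + 1)
    etab = np.zeros((L + 1, L + 1, 2 * L + 2))
    rfull = np.zeros((L + 1, L + 1, L + 1, L + 1))
    boys_buf = np.empty(L + 1)
    return _eri_prim_ws(la, ma, na, lb, mb, nb, lc, mc, nc, ld, md, nd,
                        a, b, c, d, A, B, C, D,
                        E1x, E1y, E1z, E2x, E2y, E2z, etab, rfull,
                        boys_buf)


@njit(cache=True)
def _one_electron(nbf, lmn, centers, nprim, pstart, exps, coefs,
                  atom_Z, atom_R):
    S = np.zeros((nbf, nbf))
    T = np.zeros((nbf, nbf))
    V = np.zeros((nbf, nbf))
    for i in range(nbf):
        for j in range(i + 1):
            s = 0.0
            t = 0.0
            v = 0.0
            for pi in range(pstart[i], pstart[i] + nprim[i]):
                for pj in range(pstart[j], pstart[j] + nprim[j]):
                    cc = coefs[pi] * coefs[pj]
                    s += cc * _overlap_prim(
                        lmn[i, 0], lmn[i, 1], lmn[i, 2],
                        lmn[j, 0], lmn[j, 1], lmn[j, 2],
                        exps[pi], exps[pj], centers[i], centers[j])
                    t += cc * _kinetic_prim(
                        lmn[i, 0], lmn[i, 1], lmn[i, 2],
                        lmn[j, 0], lmn[j, 1], lmn[j, 2],
                        exps[pi], exps[pj], centers[i], centers[j])
                    for k in range(atom_Z.shape[0]):
                        v -= atom_Z[k] * cc * _nuclear_prim(
                            lmn[i, 0], lmn[i, 1], lmn[i, 2],
                            lmn[j, 0], lmn[j, 1], lmn[j, 2],
                            exps[pi], exps[pj],
                            centers[i], centers[j], atom_R[k])
            S[i, j] = S[j, i] = s
            T[i, j] = T[j, i] = t
            V[i, j] = V[j, i] = v
    return S, T, V


@njit(cache=True)
def _contracted_eri_ws(i, j, k, l, lmn, centers, nprim, pstart, exps, coefs,
                       E1x, E1y, E1z, E2x, E2y, E2z, etab, rfull, boys_buf):
    total = 0.0
    AB2 = 0.0
    CD2 = 0.0
    for ax in range(3):
        AB2 += (centers[i, ax] - centers[j, ax]) ** 2
        CD2 += (centers[k, ax] - centers[l, ax]) ** 2
    for pi in range(pstart[i], pstart[i] + nprim[i]):
        for pj in range(pstart[j], pstart[j] + nprim[j]):
            cij = coefs[pi] * coefs[pj]
            p = exps[pi] + exps[pj]
            kab = abs(cij) * math.exp(-exps[pi] * exps[pj] / p * AB2)
            if kab < 1e-16:
                continue
            for pk in range(pstart[k], pstart[k] + nprim[k]):
                for pl in range(pstart[l], pstart[l] + nprim[l]):
                    q = exps[pk] + exps[pl]
                    kcd = abs(coefs[pk] * coefs[pl]) * math.exp(
                        -exps[pk] * exps[pl] / q * CD2)
                    if kab * kcd * 34.0 / (p * q * math.sqrt(p + q)) \
                            < 1e-15:
                        continue
                    total += cij * coefs[pk] * coefs[pl] * _eri_prim_ws(
                        lmn[i, 0], lmn[i, 1], lmn[i, 2],
                        lmn[j, 0], lmn[j, 1], lmn[j, 2],
                        lmn[k, 0], lmn[k, 1], lmn[k, 2],
                        lmn[l, 0], lmn[l, 1], lmn[l, 2],
                        exps[pi], exps[pj], exps[pk], exps[pl],
                        centers[i], centers[j], centers[k], centers[l],
                        E1x, E1y, E1z, E2x, E2y, E2z, etab, rfull,
                        boys_buf)
    return total


@njit(cache=True)
def _contracted_eri(i, j, k, l, lmn, centers, nprim, pstart, exps, coefs):
    L = 0
    for q in (i, j, k, l):
        L += lmn[q, 0] + lmn[q, 1] + lmn[q, 2]
    E1x = np.zeros(2 * L + 1)
    E1y = np.zeros(2 * L + 1)
    E1z = np.zeros(2 * L + 1)
    E2x = np.zeros(2 * L + 1)
    E2y = np.zeros(2 * L + 1)
    E2z = np.zeros(2 * L + 1)
    etab = np.zeros((L + 1, L + 1, 2 * L + 2))
    rfull = np.zeros((L + 1, L + 1, L + 1, L + 1))
    boys_buf = np.empty(L + 1)
    return _contracted_eri_ws(i, j, k, l, lmn, centers, nprim, pstart,
                              exps, coefs, E1x, E1y, E1z, E2x, E2y, E2z,
                              etab, rfull, boys_buf)


@njit(cache=True)
def _two_electron(nbf, lmn, centers, nprim, pstart, exps, coefs, screen_tol):
    eri = np.zeros((nbf, nbf, nbf, nbf))
    # shared workspaces sized by the largest total angular momentum
    Lmax = 0
    for i in range(nbf):
        s = lmn[i, 0] + lmn[i, 1] + lmn[i, 2]
        if s > Lmax:
            Lmax = s
    L = 4 * Lmax
    E1x = np.zeros(2 * L + 2)
    E1y = np.zeros(2 * L + 2)
    E1z = np.zeros(2 * L + 2)
    E2x = np.zeros(2 * L + 2)
    E2y = np.zeros(2 * L + 2)
    E2z = np.zeros(2 * L + 2)
    etab = np.zeros((L + 2, L + 2, 2 * L + 3))
    rfull = np.zeros((L + 2, L + 2, L + 2, L + 2))
    boys_buf = np.empty(L + 2)
    # Schwarz screening bounds
    diag = np.zeros((nbf, nbf))
    for i in range(nbf):
        for j in range(i + 1):
            v = _contracted_eri_ws(i, j, i, j, lmn, centers, nprim, pstart,
                                   exps, coefs, E1x, E1y, E1z, E2x, E2y,
                                   E2z, etab, rfull, boys_buf)
            d = math.sqrt(abs(v))
            diag[i, j] = d
            diag[j, i] = d
    for i in range(nbf):
        for j in range(i + 1):
            for k in range(i + 1):
                if k == i:
                    lmax = j
                else:
                    lmax = k
                for l in range(lmax + 1):
                    if diag[i, j] * diag[k, l] < screen_tol:
                        continue
                    v = _contracted_eri_ws(i, j, k, l, lmn, centers, nprim,
                                           pstart, exps, coefs, E1x, E1y,
                                           E1z, E2x, E2y, E2z, etab, rfull,
                                           boys_buf)
                    eri[i, j, k, l] = v
                    eri[j, i, k, l] = v
                    eri[i, j, l, k] = v
                    eri[j, i, l, k] = v
                    eri[k, l, i, j] = v
                    eri[l, k, i, j] = v
                    eri[k, l, j, i] = v
                    eri[l, k, j, i] = v
    return eri


def build_integrals(basis, molecule, screen_tol=1e-12):
    """Compute S, T, V_ne and the ERI tensor for a ContractedBasis.

    Parameters
    ----------
    basis : ContractedBasis
        Flattened per-basis-function primitive data (see `elfx.basis`).
    molecule : Molecule
        Supplies nuclear charges and positions (bohr).

    Returns
    -------
    (S, T, V, eri) : ndarrays of shape (n,n), (n,n), (n,n), (n,n,n,n)
    """
    Z = np.asarray(molecule.charges, dtype=np.float64)
    R = np.asarray(molecule.coords, dtype=np.float64)
    S, T, V = _one_electron(basis.nbf, basis.lmn, basis.centers,
                            basis.nprim, basis.pstart, basis.exps,
                            basis.coefs, Z, R)
    eri = _two_electron(basis.nbf, basis.lmn, basis.centers, basis.nprim,
                        basis.pstart, basis.exps, basis.coefs, screen_tol)
    return S, T, V, eri
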