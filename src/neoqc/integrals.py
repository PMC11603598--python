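"""Gaussian integral engine (McMurchie-Davidson scheme).

Evaluates overlap, kinetic, point-charge attraction and two-, three- and
four-centre Coulomb integrals over contracted spherical Gaussian shells of
arbitrary angular momentum.  Cartesian primitives are expanded in Hermite
Gaussians; Coulomb kernels reduce to Boys-function derivatives ``R_tuv``.
Three- and two-index fitting integrals reuse the four-centre code by pairing
each auxiliary function with a unit (zero-exponent) s "shell".

Contracted spherical AOs are renormalised to unit self-overlap, so shipped
contraction coefficients only need to be correct in ratio.  All quantities in
atomic units.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import gammainc, gammaln


# ------------------------------------------------------------- bookkeeping

@lru_cache(maxsize=None)
def cart_components(l: int) -> tuple:
    """Cartesian monomials of degree l in canonical order."""
    out = []
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            out.append((lx, ly, l - lx - ly))
    return tuple(out)


def _dfact(n: int) -> float:
    """(n)!! with (-1)!! = 1."""
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def prim_norm(l: int, a: float) -> float:
    """Norm of an x^l-type cartesian primitive; unit for the zero-exponent
    dummy used in fitting integrals."""
    if a == 0.0:
        return 1.0
    return (2 * a / math.pi) ** 0.75 * (4 * a) ** (l / 2) / math.sqrt(_dfact(2 * l - 1))


class _DummyShell:
    """Constant-1 's shell' (zero exponent) pairing partner for 2c/3c ERIs."""
    l = 0
    exps = np.array([0.0])
    coefs = np.array([1.0])
    nfunc = 1
    ncart = 1


_DUMMY = _DummyShell()


@lru_cache(maxsize=None)
def solid_harmonic_transform(l: int) -> np.ndarray:
    """Real solid harmonic expansion matrix T[m, cart] (m ordered -l..l).

    Row scale is arbitrary (functions are renormalised downstream); relative
    coefficients follow the standard closed-form expansion of real solid
    harmonics in cartesian monomials.
    """
    comps = cart_components(l)
    T = np.zeros((2 * l + 1, len(comps)))
    idx = {c: k for k, c in enumerate(comps)}
    from math import comb, floor
    for m in range(-l, l + 1):
        am = abs(m)
        row = l + m
        if m >= 0:
            vs = [float(v) for v in range(0, am // 2 + 1)]
            vm = 0.0
        else:
            vs = [v + 0.5 for v in range(0, (am - 1) // 2 + 1)]
            vm = 0.5
        for t in range((l - am) // 2 + 1):
            for u in range(t + 1):
                for v in vs:
                    c = ((-1.0) ** (t + v - vm) * 0.25 ** t * comb(l, t)
                         * comb(l - t, am + t) * comb(t, u) * comb(am, int(2 * v)))
                    lx = int(2 * t + am - 2 * (u + v))
                    ly = int(2 * (u + v))
                    lz = l - 2 * t - am
                    T[row, idx[(lx, ly, lz)]] += c
    return T


# ---------------------------------------------------------------- Boys / R

def boys(L: int, x: np.ndarray) -> np.ndarray:
    """Boys functions F_0..F_L, shape (L+1,) + x.shape.

    Top order from the regularised lower incomplete gamma, then downward
    recursion; series near x = 0.
    """
    x = np.asarray(x, dtype=float)
    F = np.empty((L + 1,) + x.shape)
    nu = L + 0.5
    small = x < 1e-13
    xs = np.where(small, 1.0, x)
    top = 0.5 * np.exp(gammaln(nu)) * gammainc(nu, xs) / xs ** nu
    F[L] = np.where(small, 1.0 / (2 * L + 1) - x / (2 * L + 3), top)
    ex = np.exp(-x)
    for n in range(L, 0, -1):
        F[n - 1] = (2.0 * x * F[n] + ex) / (2 * n - 1)
    return F


def hermite_R(L: int, alpha: np.ndarray, PQ: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R_tuv, vectorised over the leading axis.

    alpha: (n,); PQ: (n, 3).  Returns R of shape (n, L+1, L+1, L+1).
    """
    n = alpha.shape[0]
    X, Y, Z = PQ[:, 0], PQ[:, 1], PQ[:, 2]
    x = alpha * np.einsum("ij,ij->i", PQ, PQ)
    F = boys(L, x)
    Rn = np.zeros((L + 2, n, L + 1, L + 1, L + 1))
    pw = np.ones(n)
    for m in range(L + 1):
        Rn[m, :, 0, 0, 0] = pw * F[m]
        pw = pw * (-2.0 * alpha)
    for m in range(L - 1, -1, -1):
        rem = L - m
        for t in range(1, rem + 1):
            base = Rn[m + 1]
            Rn[m, :, t, 0, 0] = X * base[:, t - 1, 0, 0]
            if t > 1:
                Rn[m, :, t, 0, 0] += (t - 1) * base[:, t - 2, 0, 0]
        for t in range(rem + 1):
            for u in range(1, rem - t + 1):
                base = Rn[m + 1]
                Rn[m, :, t, u, 0] = Y * base[:, t, u - 1, 0]
                if u > 1:
                    Rn[m, :, t, u, 0] += (u - 1) * base[:, t, u - 2, 0]
            for u in range(rem - t + 1):
                for v in range(1, rem - t - u + 1):
                    base = Rn[m + 1]
                    Rn[m, :, t, u, v] = Z * base[:, t, u, v - 1]
                    if v > 1:
                        Rn[m, :, t, u, v] += (v - 1) * base[:, t, u, v - 2]
    return Rn[0]


# ---------------------------------------------------- Hermite expansion E

def _e1d(l1: int, l2: int, a: float, b: float, AB: float) -> np.ndarray:
    """E[i, j, t] Hermite expansion coefficients for one direction."""
    p = a + b
    E = np.zeros((l1 + 1, l2 + 1, l1 + l2 + 1))
    E[0, 0, 0] = math.exp(-a * b / p * AB * AB)
    PA = -b * AB / p
    PB = a * AB / p
    inv2p = 0.5 / p
    for i in range(1, l1 + 1):
        for t in range(i + 1):
            val = PA * E[i - 1, 0, t]
            if t > 0:
                val += inv2p * E[i - 1, 0, t - 1]
            if t + 1 <= i - 1:
                val += (t + 1) * E[i - 1, 0, t + 1]
            E[i, 0, t] = val
    for j in range(1, l2 + 1):
        for i in range(l1 + 1):
            for t in range(i + j + 1):
                val = PB * E[i, j - 1, t]
                if t > 0:
                    val += inv2p * E[i, j - 1, t - 1]
                if t + 1 <= i + j - 1:
                    val += (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = val
    return E


class ShellPair:
    """Primitive-pair data for a pair of centred shells.

    For every primitive product stores the total exponent, Gaussian-product
    centre, weighted coefficient and the flattened Hermite expansion tensor
    E[cart_ab, tuv] over the (L+1)^3 Hermite cube, L = l1 + l2.
    """

    def __init__(self, A, shell1, B, shell2):
        self.A, self.B = np.asarray(A, float), np.asarray(B, float)
        self.sh1, self.sh2 = shell1, shell2
        l1, l2 = shell1.l, shell2.l
        self.L = l1 + l2
        c1s = cart_components(l1)
        c2s = cart_components(l2)
        AB = self.A - self.B
        ps, Ps, cs, Es = [], [], [], []
        side = self.L + 1
        for a, ca in zip(shell1.exps, shell1.coefs):
            na = prim_norm(l1, a)
            for b, cb in zip(shell2.exps, shell2.coefs):
                nb = prim_norm(l2, b)
                p = a + b
                P = (a * self.A + b * self.B) / p
                ex = _e1d(l1, l2, a, b, AB[0])
                ey = _e1d(l1, l2, a, b, AB[1])
                ez = _e1d(l1, l2, a, b, AB[2])
                E = np.zeros((len(c1s) * len(c2s), side, side, side))
                k = 0
                for (ix, iy, iz) in c1s:
                    for (jx, jy, jz) in c2s:
                        E[k, :ix + jx + 1, :iy + jy + 1, :iz + jz + 1] = (
                            ex[ix, jx, :ix + jx + 1, None, None]
                            * ey[iy, jy, None, :iy + jy + 1, None]
                            * ez[iz, jz, None, None, :iz + jz + 1])
                        k += 1
                ps.append(p)
                Ps.append(P)
                cs.append(ca * cb * na * nb)
                Es.append(E.reshape(len(c1s) * len(c2s), -1))
        self.p = np.array(ps)
        self.P = np.array(Ps)
        self.c = np.array(cs)
        self.E = np.array(Es)                      # (nprim, ncart12, ntuv)
        self.n1, self.n2 = len(c1s), len(c2s)

    # Hermite-cube index helpers -------------------------------------
    def tuv_indices(self):
        side = self.L + 1
        t, u, v = np.meshgrid(np.arange(side), np.arange(side), np.arange(side),
                              indexing="ij")
        return t.ravel(), u.ravel(), v.ravel()


@lru_cache(maxsize=None)
def _tuv_grid(L: int):
    side = L + 1
    t, u, v = np.meshgrid(np.arange(side), np.arange(side), np.arange(side),
                          indexing="ij")
    return t.ravel(), u.ravel(), v.ravel()


def eri_quartet(bra: ShellPair, ket: ShellPair) -> np.ndarray:
    """Contracted cartesian (ab|cd) block, shape (ncart_ab, ncart_cd)."""
    Lb, Lk = bra.L, ket.L
    L = Lb + Lk
    tb, ub, vb = _tuv_grid(Lb)
    tk, uk, vk = _tuv_grid(Lk)
    sign = (-1.0) ** (tk + uk + vk)
    nb, nk = bra.p.shape[0], ket.p.shape[0]
    # all primitive combinations, bra-major
    pb = np.repeat(bra.p, nk)
    pk = np.tile(ket.p, nb)
    Pb = np.repeat(bra.P, nk, axis=0)
    Pk = np.tile(ket.P, (nb, 1))
    alpha = pb * pk / (pb + pk)
    pref = (2.0 * math.pi ** 2.5 / (pb * pk * np.sqrt(pb + pk))
            * np.repeat(bra.c, nk) * np.tile(ket.c, nb))
    R = hermite_R(L, alpha, Pb - Pk)
    # G[n, tuv_b, tuv_k] = R[n, tb+tk, ub+uk, vb+vk]
    G = R[:, tb[:, None] + tk[None, :], ub[:, None] + uk[None, :],
          vb[:, None] + vk[None, :]]
    Eb = np.repeat(bra.E, nk, axis=0)
    Ek = np.tile(ket.E, (nb, 1, 1)) * sign[None, None, :]
    tmp = np.einsum("nbm,nmk->nbk", Eb, G, optimize=True)
    out = np.einsum("n,nbk,nck->bc", pref, tmp, Ek, optimize=True)
    return out


# ---------------------------------------------------------------- AO basis

class AOBasis:
    """A list of centred spherical shells with cached pair data.

    ``entries`` is a list of ``(center_bohr, Shell, atom_index)``.
    Public matrices are over renormalised spherical AOs.
    """

    def __init__(self, entries):
        self.entries = [(np.asarray(c, float), s, int(ia)) for c, s, ia in entries]
        self.offsets = []
        n = 0
        for _, s, _ in self.entries:
            self.offsets.append(n)
            n += 2 * s.l + 1
        self.nbf = n
        self._pair_cache: dict = {}
        self._norms = None

    @property
    def ao_atoms(self) -> np.ndarray:
        out = np.empty(self.nbf, dtype=int)
        for (c, s, ia), off in zip(self.entries, self.offsets):
            out[off:off + 2 * s.l + 1] = ia
        return out

    def centers(self) -> np.ndarray:
        return np.array([c for c, _, _ in self.entries])

    def _pair(self, i: int, j: int) -> ShellPair:
        key = (i, j)
        sp = self._pair_cache.get(key)
        if sp is None:
            ci, si, _ = self.entries[i]
            cj, sj, _ = self.entries[j]
            sp = ShellPair(ci, si, cj, sj)
            self._pair_cache[key] = sp
        return sp

    # -------------------------------------------------- normalisation
    def norms(self) -> np.ndarray:
        if self._norms is None:
            S = self._overlap_raw()
            self._norms = 1.0 / np.sqrt(np.diag(S))
        return self._norms

    def _sph_block(self, blk, s1, s2):
        T1 = solid_harmonic_transform(s1.l)
        T2 = solid_harmonic_transform(s2.l)
        return T1 @ blk @ T2.T

    # -------------------------------------------------- one-electron
    def _one_electron(self, kind, charges=None):
        M = np.zeros((self.nbf, self.nbf))
        for i, (ci, si, _) in enumerate(self.entries):
            for j in range(i, len(self.entries)):
                cj, sj, _ = self.entries[j]
                blk = _one_e_block(ci, si, cj, sj, kind, charges)
                sb = self._sph_block(blk, si, sj)
                oi, oj = self.offsets[i], self.offsets[j]
                M[oi:oi + sb.shape[0], oj:oj + sb.shape[1]] = sb
                if j != i:
                    M[oj:oj + sb.shape[1], oi:oi + sb.shape[0]] = sb.T
        return M

    def _overlap_raw(self):
        return self._one_electron("overlap")

    def overlap(self) -> np.ndarray:
        n = self.norms()
        return n[:, None] * self._overlap_raw() * n[None, :]

    def kinetic(self) -> np.ndarray:
        n = self.norms()
        return n[:, None] * self._one_electron("kinetic") * n[None, :]

    def attraction(self, charges) -> np.ndarray:
        """Sum_C q_C (mu| 1/|r-C| |nu); pass signed charges [(q, center), ...]."""
        n = self.norms()
        return n[:, None] * self._one_electron("attraction", charges) * n[None, :]

    def dipole(self) -> np.ndarray:
        """Moment integrals <mu|r_k|nu> about the origin, shape (3, nbf, nbf)."""
        n = self.norms()
        out = np.empty((3, self.nbf, self.nbf))
        for k in range(3):
            out[k] = n[:, None] * self._one_electron(("dipole", k)) * n[None, :]
        return out


def _one_e_block(ci, si, cj, sj, kind, charges):
    l1, l2 = si.l, sj.l
    c1s, c2s = cart_components(l1), cart_components(l2)
    out = np.zeros((len(c1s), len(c2s)))
    AB = np.asarray(ci) - np.asarray(cj)
    for a, ca in zip(si.exps, si.coefs):
        na = prim_norm(l1, a)
        for b, cb in zip(sj.exps, sj.coefs):
            nb = prim_norm(l2, b)
            p = a + b
            w = ca * cb * na * nb
            if kind == "kinetic":
                ex = _e1d(l1, l2 + 2, a, b, AB[0])
                ey = _e1d(l1, l2 + 2, a, b, AB[1])
                ez = _e1d(l1, l2 + 2, a, b, AB[2])
            else:
                ex = _e1d(l1, l2, a, b, AB[0])
                ey = _e1d(l1, l2, a, b, AB[1])
                ez = _e1d(l1, l2, a, b, AB[2])
            if kind == "attraction":
                P = (a * np.asarray(ci) + b * np.asarray(cj)) / p
                Lc = l1 + l2
                for q, C in charges:
                    R = hermite_R(Lc, np.array([p]),
                                  (P - np.asarray(C))[None, :])[0]
                    for k1, (ix, iy, iz) in enumerate(c1s):
                        for k2, (jx, jy, jz) in enumerate(c2s):
                            acc = 0.0
                            for t in range(ix + jx + 1):
                                for u in range(iy + jy + 1):
                                    for v in range(iz + jz + 1):
                                        acc += (ex[ix, jx, t] * ey[iy, jy, u]
                                                * ez[iz, jz, v] * R[t, u, v])
                            out[k1, k2] += w * q * (2 * math.pi / p) * acc
                continue
            sfac = (math.pi / p) ** 1.5
            if isinstance(kind, tuple) and kind[0] == "dipole":
                P = (a * np.asarray(ci) + b * np.asarray(cj)) / p
                kdir = kind[1]
                es = (ex, ey, ez)
                for k1, (ix, iy, iz) in enumerate(c1s):
                    ii = (ix, iy, iz)
                    for k2, (jx, jy, jz) in enumerate(c2s):
                        jj = (jx, jy, jz)
                        val = 1.0
                        for d in range(3):
                            e0 = es[d][ii[d], jj[d], 0]
                            if d == kdir:
                                e1 = (es[d][ii[d], jj[d], 1]
                                      if ii[d] + jj[d] >= 1 else 0.0)
                                val *= e0 * P[d] + e1
                            else:
                                val *= e0
                        out[k1, k2] += w * sfac * val
                continue
            for k1, (ix, iy, iz) in enumerate(c1s):
                for k2, (jx, jy, jz) in enumerate(c2s):
                    if kind == "overlap":
                        out[k1, k2] += w * sfac * (ex[ix, jx, 0] * ey[iy, jy, 0]
                                                   * ez[iz, jz, 0])
                    else:  # kinetic
                        def t1d(e, i, j):
                            val = b * (2 * j + 1) * e[i, j, 0] - 2 * b * b * e[i, j + 2, 0]
                            if j >= 2:
                                val -= 0.5 * j * (j - 1) * e[i, j - 2, 0]
                            return val
                        tx = t1d(ex, ix, jx)
                        ty = t1d(ey, iy, jy)
                        tz = t1d(ez, iz, jz)
                        out[k1, k2] += w * sfac * (
                            tx * ey[iy, jy, 0] * ez[iz, jz, 0]
                            + ex[ix, jx, 0] * ty * ez[iz, jz, 0]
                            + ex[ix, jx, 0] * ey[iy, jy, 0] * tz)
    return out


# ------------------------------------------------------- 4c / 3c / 2c ERI

class SizeGuardError(MemoryError):
    pass


def _check_size(dims, cap=8e7):
    n = float(np.prod([float(d) for d in dims]))
    if n > cap:
        raise SizeGuardError(
            f"requested integral tensor of {n:.2e} elements "
            f"(~{n * 8 / 1e9:.1f} GB) exceeds the size guard of {cap:.0e}")


def _sph_quartet(blk, s1, s2, s3, s4):
    b = blk.reshape(s1.ncart if hasattr(s1, "ncart") else 1, -1)
    n1 = len(cart_components(s1.l))
    n2 = len(cart_components(s2.l))
    n3 = len(cart_components(s3.l))
    n4 = len(cart_components(s4.l))
    b = blk.reshape(n1, n2, n3, n4)
    T1 = solid_harmonic_transform(s1.l)
    T2 = solid_harmonic_transform(s2.l)
    T3 = solid_harmonic_transform(s3.l)
    T4 = solid_harmonic_transform(s4.l)
    return np.einsum("ai,bj,ck,dl,ijkl->abcd", T1, T2, T3, T4, b, optimize=True)


def eri_coulomb(basisA: AOBasis, basisB: AOBasis | None = None,
                cap: float = 8e7) -> np.ndarray:
    """Full four-index Coulomb tensor (ab|cd) with bra AOs from basisA and
    ket AOs from basisB (defaults to basisA).  Positive 1/r12 kernel; the
    caller applies charge signs."""
    same = basisB is None or basisB is basisA
    B = basisA if same else basisB
    _check_size([basisA.nbf, basisA.nbf, B.nbf, B.nbf], cap)
    out = np.zeros((basisA.nbf, basisA.nbf, B.nbf, B.nbf))
    nA = len(basisA.entries)
    nB = len(B.entries)
    bra_pairs = [(i, j) for i in range(nA) for j in range(i, nA)]
    ket_pairs = [(k, l) for k in range(nB) for l in range(k, nB)]
    for bi, (i, j) in enumerate(bra_pairs):
        bp = basisA._pair(i, j)
        si, sj = basisA.entries[i][1], basisA.entries[j][1]
        ket_start = bi if same else 0
        for (k, l) in ket_pairs[ket_start:]:
            kp = B._pair(k, l)
            sk, sl = B.entries[k][1], B.entries[l][1]
            blk = eri_quartet(bp, kp)
            sb = _sph_quartet(blk, si, sj, sk, sl)
            _scatter(out, sb, basisA.offsets[i], basisA.offsets[j],
                     B.offsets[k], B.offsets[l], same)
    nAo = basisA.norms()
    nBo = B.norms()
    out *= nAo[:, None, None, None] * nAo[None, :, None, None]
    out *= nBo[None, None, :, None] * nBo[None, None, None, :]
    return out


def _scatter(out, sb, oi, oj, ok, ol, same):
    di, dj, dk, dl = sb.shape
    out[oi:oi + di, oj:oj + dj, ok:ok + dk, ol:ol + dl] = sb
    out[oj:oj + dj, oi:oi + di, ok:ok + dk, ol:ol + dl] = sb.transpose(1, 0, 2, 3)
    out[oi:oi + di, oj:oj + dj, ol:ol + dl, ok:ok + dk] = sb.transpose(0, 1, 3, 2)
    out[oj:oj + dj, oi:oi + di, ol:ol + dl, ok:ok + dk] = sb.transpose(1, 0, 3, 2)
    if same:
        out[ok:ok + dk, ol:ol + dl, oi:oi + di, oj:oj + dj] = sb.transpose(2, 3, 0, 1)
        out[ol:ol + dl, ok:ok + dk, oi:oi + di, oj:oj + dj] = sb.transpose(3, 2, 0, 1)
        out[ok:ok + dk, ol:ol + dl, oj:oj + dj, oi:oi + di] = sb.transpose(2, 3, 1, 0)
        out[ol:ol + dl, ok:ok + dk, oj:oj + dj, oi:oi + di] = sb.transpose(3, 2, 1, 0)


def three_center(aux: AOBasis, basis: AOBasis) -> np.ndarray:
    """(A|mu nu) three-index Coulomb integrals, shape (naux, nbf, nbf)."""
    _check_size([aux.nbf, basis.nbf, basis.nbf])
    out = np.zeros((aux.nbf, basis.nbf, basis.nbf))
    nb = len(basis.entries)
    ket_pairs = [(k, l) for k in range(nb) for l in range(k, nb)]
    kps = {}
    for ai, (cA, sA, _) in enumerate(aux.entries):
        bp = ShellPair(cA, sA, cA, _DUMMY)
        TA = solid_harmonic_transform(sA.l)
        for (k, l) in ket_pairs:
            kp = kps.get((k, l))
            if kp is None:
                kp = basis._pair(k, l)
                kps[(k, l)] = kp
            sk, sl = basis.entries[k][1], basis.entries[l][1]
            blk = eri_quartet(bp, kp)          # (ncartA*1, ncart_kl)
            n3 = len(cart_components(sk.l))
            n4 = len(cart_components(sl.l))
            b = blk.reshape(len(cart_components(sA.l)), n3, n4)
            T3 = solid_harmonic_transform(sk.l)
            T4 = solid_harmonic_transform(sl.l)
            sb = np.einsum("ai,ck,dl,ikl->acd", TA, T3, T4, b, optimize=True)
            oA, ok, ol = aux.offsets[ai], basis.offsets[k], basis.offsets[l]
            out[oA:oA + sb.shape[0], ok:ok + sb.shape[1], ol:ol + sb.shape[2]] = sb
            if k != l:
                out[oA:oA + sb.shape[0], ol:ol + sb.shape[2], ok:ok + sb.shape[1]] = \
                    sb.transpose(0, 2, 1)
    na = aux.norms()
    nb_ = basis.norms()
    out *= na[:, None, None]
    out *= nb_[None, :, None] * nb_[None, None, :]
    return out


def two_center(aux: AOBasis) -> np.ndarray:
    """(A|B) Coulomb metric over auxiliary functions."""
    n = len(aux.entries)
    out = np.zeros((aux.nbf, aux.nbf))
    for i, (cA, sA, _) in enumerate(aux.entries):
        bp = ShellPair(cA, sA, cA, _DUMMY)
        TA = solid_harmonic_transform(sA.l)
        for j in range(i, n):
            cB, sB, _ = aux.entries[j]
            kp = ShellPair(cB, sB, cB, _DUMMY)
            TB = solid_harmonic_transform(sB.l)
            blk = eri_quartet(bp, kp)
            sb = TA @ blk @ TB.T
            oi, oj = aux.offsets[i], aux.offsets[j]
            out[oi:oi + sb.shape[0], oj:oj + sb.shape[1]] = sb
            if j != i:
                out[oj:oj + sb.shape[1], oi:oi + sb.shape[0]] = sb.T
    na = aux.norms()
    return na[:, None] * out * na[None, :]
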