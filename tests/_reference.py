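"""Standalone textbook reference implementations used as independent oracles.

These deliberately avoid the package's SCF/MP2 code paths: the RHF loop is a
damped Roothaan fixed-point iteration with an explicit symmetric
orthogonalizer, and the MP2 reference is a spin-orbital enumeration sum.
Only the AO integrals are shared with the package (they are themselves pinned
against literature values and quadrature elsewhere in the suite).
"""

import numpy as np


def reference_rhf(S, h, eri, n_pairs, e_nuc=0.0, max_iter=500, tol=1e-11,
                  damping=0.35):
    """Damped closed-shell Roothaan iteration; returns (energy, eps, C)."""
    w, V = np.linalg.eigh(S)
    X = V @ np.diag(w ** -0.5) @ V.T
    F = h
    P = None
    E_old = 0.0
    for _ in range(max_iter):
        Fp = X.T @ F @ X
        eps, Cp = np.linalg.eigh(Fp)
        C = X @ Cp
        Cocc = C[:, :n_pairs]
        P_new = 2.0 * Cocc @ Cocc.T
        P = P_new if P is None else (1 - damping) * P_new + damping * P
        J = np.einsum("mnls,ls->mn", eri, P)
        K = np.einsum("mlns,ls->mn", eri, P)
        F = h + J - 0.5 * K
        E = 0.5 * np.sum(P * (h + F)) + e_nuc
        if abs(E - E_old) < tol:
            return E, eps, C
        E_old = E
    raise RuntimeError("reference RHF did not converge")


def reference_mp2_spinorbital(eps, n_pairs, K_mo_full):
    """Closed-shell MP2 by brute-force spin-orbital enumeration.

    K_mo_full[p, q, r, s] = (pq|rs) over all spatial orbitals.
    """
    n = len(eps)
    so = [(p, s) for p in range(n) for s in (0, 1)]
    occ = [k for k, (p, _) in enumerate(so) if p < n_pairs]
    vir = [k for k, (p, _) in enumerate(so) if p >= n_pairs]

    def asym(p, q, r, s):
        (pi, ps), (qi, qs), (ri, rs), (si, ss) = so[p], so[q], so[r], so[s]
        out = 0.0
        if ps == rs and qs == ss:
            out += K_mo_full[pi, ri, qi, si]
        if ps == ss and qs == rs:
            out -= K_mo_full[pi, si, qi, ri]
        return out

    e = np.array([eps[p] for p, _ in so])
    E = 0.0
    for ii, i in enumerate(occ):
        for j in occ[ii + 1:]:
            for aa, a in enumerate(vir):
                for b in vir[aa + 1:]:
                    w = asym(i, j, a, b)
                    if w:
                        E += w * w / (e[i] + e[j] - e[a] - e[b])
    return E
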