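"""Canonical NEO-MP2: the three correlation channels and a sum-over-states
oracle.

Second-order perturbation theory on the NEO-HF reference decouples into an
electron-electron, an electron-proton and a proton-proton channel, because
double excitations of the three classes do not mix through the fluctuation
potential.  Spin-adapted spatial-orbital forms (electrons doubly occupied,
protons singly occupied and high-spin):

* ee:  sum_ijab K_iajb (2 K_iajb - K_ibja) / (e_i + e_j - e_a - e_b)
* pp:  (1/4) sum_i'j'a'b' (K - K^T)^2 / (e_i' + e_j' - e_a' - e_b')
* ep:  2 sum_iai'a' |K_ia,i'a'|^2 / (e_i + e_i' - e_a - e_a')

Every prefactor is pinned by :func:`rspt2_oracle`, an explicit enumeration of
doubly excited determinant products with Slater-Condon matrix elements; the
oracle is the ground truth the closed forms are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np


class DegenerateDenominatorError(ArithmeticError):
    pass


@dataclass
class CorrelationResult:
    """Channel-resolved NEO-MP2 energies (hartree)."""

    E_ee: float = 0.0
    E_ep: float = 0.0
    E_pp: float = 0.0
    pair_energies_ee: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.E_ee + self.E_ep + self.E_pp


def _check_denominator(D, what):
    bad = np.abs(D) < 1e-8
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise DegenerateDenominatorError(
            f"near-degenerate {what} denominator |D| < 1e-8 at indices {tuple(idx)}")


def mp2_ee(K: np.ndarray, eps_occ: np.ndarray, eps_virt: np.ndarray):
    """Closed-shell electronic MP2 from K[i,a,j,b] = (ia|jb).

    Returns (energy, pair_energy_matrix).  Zero virtual space gives zero.
    """
    no, nv = K.shape[0], K.shape[1]
    if nv == 0 or no == 0:
        return 0.0, np.zeros((no, no))
    D = (eps_occ[:, None, None, None] + eps_occ[None, None, :, None]
         - eps_virt[None, :, None, None] - eps_virt[None, None, None, :])
    _check_denominator(D, "ee")
    T = K / D
    contrib = T * (2.0 * K - K.transpose(0, 3, 2, 1))
    pair = contrib.sum(axis=(1, 3))
    return float(pair.sum()), pair


def mp2_pp(K: np.ndarray, eps_occ: np.ndarray, eps_virt: np.ndarray) -> float:
    """Same-spin (high-spin) proton-proton MP2; exactly zero for one proton."""
    no, nv = K.shape[0], K.shape[1]
    if no < 2 or nv == 0:
        return 0.0
    D = (eps_occ[:, None, None, None] + eps_occ[None, None, :, None]
         - eps_virt[None, :, None, None] - eps_virt[None, None, None, :])
    _check_denominator(D, "pp")
    A = K - K.transpose(0, 3, 2, 1)       # <i'j'||a'b'> in (i,a,j,b) layout
    return float(0.25 * (A * A / D).sum())


def mp2_ep(K: np.ndarray, eps_occ_e, eps_virt_e, eps_occ_p, eps_virt_p) -> float:
    """Electron-proton channel from K[i,a,i',a'] (attractive-operator sign).

    The factor 2 is the electron spin sum over the conserved-spin single
    excitations; squaring makes the result sign-independent of the stored
    integral convention, but the attractive sign is kept in K nonetheless.
    """
    if K.size == 0:
        return 0.0
    D = (eps_occ_e[:, None, None, None] + eps_occ_p[None, None, :, None]
         - eps_virt_e[None, :, None, None] - eps_virt_p[None, None, None, :])
    _check_denominator(D, "ep")
    return float(2.0 * (K * K / D).sum())


# ------------------------------------------------------------------ oracle

def _spin_orbitals(n_spatial, eps, two_spins=True):
    """List of (spatial index, spin) and energies; protons share one spin."""
    orbs = []
    for p in range(n_spatial):
        orbs.append((p, 0))
        if two_spins:
            orbs.append((p, 1))
    e = np.array([eps[p] for p, _ in orbs])
    return orbs, e


def _antisym(Kfull, p, q, r, s):
    """<pq||rs> over spin orbitals from spatial (pr|qs) integrals."""
    (pi, ps_), (qi, qs), (ri, rs_), (si, ss) = p, q, r, s
    out = 0.0
    if ps_ == rs_ and qs == ss:
        out += Kfull[pi, ri, qi, si]
    if ps_ == ss and qs == rs_:
        out -= Kfull[pi, si, qi, ri]
    return out


def rspt2_oracle(eps_e, n_occ_e, K_ee_full, channel="all",
                 eps_p=None, n_occ_p=0, K_pp_full=None, K_ep_full=None,
                 max_spin_orbitals=24):
    """Brute-force second-order Rayleigh-Schrodinger energy.

    Enumerates all doubly excited determinant products over spin orbitals
    (electrons: two spins; protons: one shared spin channel), evaluates the
    fluctuation-potential matrix elements by the Slater-Condon rules from
    *full* MO-basis integral tensors (all-orbital (pq|rs) layout with p,q
    bra-particle indices), and sums |W_0n|^2 / (E0 - En).

    ``K_ep_full`` carries the attractive electron-proton sign.
    """
    ne_sp = 2 * len(eps_e)
    np_sp = 0 if eps_p is None else len(eps_p)
    if ne_sp > max_spin_orbitals or np_sp > max_spin_orbitals:
        raise ValueError(
            f"oracle size guard: {ne_sp} electronic / {np_sp} nuclear spin "
            f"orbitals exceed the limit of {max_spin_orbitals}")

    e_orbs, e_eps = _spin_orbitals(len(eps_e), eps_e, two_spins=True)
    occ_e = [k for k, (p, s) in enumerate(e_orbs) if p < n_occ_e]
    vir_e = [k for k, (p, s) in enumerate(e_orbs) if p >= n_occ_e]

    E_ee = 0.0
    if channel in ("ee", "all"):
        for i, j in combinations(occ_e, 2):
            for a, b in combinations(vir_e, 2):
                w = _antisym(K_ee_full, e_orbs[i], e_orbs[j], e_orbs[a], e_orbs[b])
                if w != 0.0:
                    E_ee += w * w / (e_eps[i] + e_eps[j] - e_eps[a] - e_eps[b])

    E_pp = 0.0
    E_ep = 0.0
    if eps_p is not None and n_occ_p > 0:
        p_orbs = [(p, 0) for p in range(len(eps_p))]
        p_eps = np.asarray(eps_p)
        occ_p = list(range(n_occ_p))
        vir_p = list(range(n_occ_p, len(eps_p)))
        if channel in ("pp", "all") and K_pp_full is not None:
            for i, j in combinations(occ_p, 2):
                for a, b in combinations(vir_p, 2):
                    w = _antisym(K_pp_full, p_orbs[i], p_orbs[j],
                                 p_orbs[a], p_orbs[b])
                    if w != 0.0:
                        E_pp += w * w / (p_eps[i] + p_eps[j] - p_eps[a] - p_eps[b])
        if channel in ("ep", "all") and K_ep_full is not None:
            # one electronic single x one nuclear single; spin conserved on the
            # electronic side, a single shared spin channel on the nuclear side
            for i in occ_e:
                pi, si = e_orbs[i]
                for a in vir_e:
                    pa, sa = e_orbs[a]
                    if si != sa:
                        continue
                    for ip in occ_p:
                        for ap in vir_p:
                            w = K_ep_full[pi, pa, ip, ap]
                            if w != 0.0:
                                E_ep += w * w / (e_eps[i] + p_eps[ip]
                                                 - e_eps[a] - p_eps[ap])
    if channel == "ee":
        return E_ee
    if channel == "pp":
        return E_pp
    if channel == "ep":
        return E_ep
    return E_ee + E_ep + E_pp
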