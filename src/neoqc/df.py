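"""Density fitting for the three NEO integral blocks.

Orbital-product densities are expanded in an auxiliary Gaussian set; with the
Coulomb metric the least-squares (robust) fit gives the familiar
resolution-of-identity factorisation

    K_ia,jb ~ sum_AB  E(A|ia) [J^-1]_AB E(B|jb),

whose energy error is quadratic in the density residual.  The ee and pp
blocks use the *unified* auxiliary set (electronic + nuclear fitting
functions sharing one metric); the mixed electron-proton block is fitted in
the nuclear auxiliary set alone, which is both cheaper and markedly more
accurate for the compact proton densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .basis import BasisError, autoaux_shells, shells_for
from .integrals import AOBasis, eri_coulomb, three_center, two_center
from .system import SystemModel


@dataclass
class AuxMetric:
    """Coulomb metric J_AB over auxiliary functions with a cached solver.

    Solved by Cholesky; if the metric is numerically singular the solve falls
    back to an eigenvalue-filtered pseudo-inverse (eigenvalues below
    ``eig_floor`` discarded) with a warning.
    """

    J: np.ndarray
    eig_floor: float = 1e-10

    def __post_init__(self):
        self._cho = None
        self._pinv = None
        w = np.linalg.eigvalsh(self.J)
        if w[0] <= self.eig_floor * max(w[-1], 1.0):
            self._prepare_pinv()
            return
        try:
            self._cho = sla.cho_factor(self.J)
        except np.linalg.LinAlgError:
            self._prepare_pinv()

    def _prepare_pinv(self):
        warnings.warn("auxiliary metric is ill-conditioned; using an "
                      "eigenvalue-filtered pseudo-solve", RuntimeWarning)
        w, V = np.linalg.eigh(self.J)
        keep = w > self.eig_floor * w.max()
        self._pinv = (V[:, keep] / w[keep]) @ V[:, keep].T

    @property
    def is_singular(self) -> bool:
        return self._pinv is not None

    def solve(self, E: np.ndarray) -> np.ndarray:
        """Fit coefficients d = J^-1 E (E may have trailing axes)."""
        shape = E.shape
        flat = E.reshape(shape[0], -1)
        if self._cho is not None:
            d = sla.cho_solve(self._cho, flat)
        else:
            d = self._pinv @ flat
        return d.reshape(shape)

    def half_solve(self, E: np.ndarray) -> np.ndarray:
        """Whitened tensor B = L^-1 E with J = L L^T, so that B^T B equals
        E^T J^-1 E; eigenvalue-filtered square root in the singular case."""
        shape = E.shape
        flat = E.reshape(shape[0], -1)
        if self._cho is not None:
            L = np.linalg.cholesky(self.J)
            B = sla.solve_triangular(L, flat, lower=True)
        else:
            w, V = np.linalg.eigh(self.J)
            keep = w > self.eig_floor * w.max()
            B = (V[:, keep] / np.sqrt(w[keep])).T @ flat
        return B.reshape((-1,) + shape[1:])


def compute_metric(aux: AOBasis, eig_floor: float = 1e-10) -> AuxMetric:
    if aux.nbf == 0:
        raise ValueError("empty auxiliary basis")
    return AuxMetric(two_center(aux), eig_floor=eig_floor)


# ------------------------------------------------------------- aux bases

def electronic_aux_basis(model: SystemModel, name: str | None = None) -> AOBasis:
    """Auxiliary AO basis on every atom.  ``autoaux-tz``/``autoaux-qz`` derive
    an even-tempered set from the orbital basis; other names resolve from the
    library (which must ship primitives)."""
    name = (name or model.aux_electronic).lower()
    entries = []
    for ia, atom in enumerate(model.atoms):
        if name.startswith("autoaux-"):
            shells = autoaux_shells(model.basis_electronic, atom.element,
                                    level=name.split("-", 1)[1])
        else:
            shells = shells_for(name, atom.element)
        for sh in shells:
            entries.append((atom.position, sh, ia))
    return AOBasis(entries)


def nuclear_aux_basis(model: SystemModel, name: str | None = None) -> AOBasis:
    """Nuclear fitting set on quantum protons only."""
    if model.n_quantum_protons == 0:
        raise ValueError("no quantum protons: nuclear auxiliary basis is empty")
    name = name or model.aux_nuclear
    entries = []
    for ia, atom in enumerate(model.atoms):
        if atom.quantum:
            for sh in shells_for(name, "H"):
                entries.append((atom.position, sh, ia))
    return AOBasis(entries)


def unified_aux_basis(model: SystemModel, electronic_name: str | None = None,
                      nuclear_name: str | None = None) -> AOBasis:
    """Concatenated electronic + nuclear fitting sets sharing one metric."""
    e = electronic_aux_basis(model, electronic_name)
    entries = list(e.entries)
    if model.n_quantum_protons > 0:
        entries += list(nuclear_aux_basis(model, nuclear_name).entries)
    return AOBasis(entries)


# --------------------------------------------------------- MO transforms

def compute_three_index(aux: AOBasis, ao: AOBasis, C_left: np.ndarray,
                        C_right: np.ndarray) -> np.ndarray:
    """E(A|ia) in the MO basis: half-transform the AO three-index tensor."""
    if C_left.shape[0] != ao.nbf or C_right.shape[0] != ao.nbf:
        raise ValueError("MO coefficient dimension does not match the AO basis")
    B = three_center(aux, ao)
    return np.einsum("Amn,mi,na->Aia", B, C_left, C_right, optimize=True)


def fit_and_assemble(E_bra: np.ndarray, metric: AuxMetric,
                     E_ket: np.ndarray | None = None) -> np.ndarray:
    """Robust-fitted four-index block K[ia,jb] = E_bra^T J^-1 E_ket.

    With the Coulomb metric the robust three-term expression collapses to
    this symmetric form.  Shapes: E (naux, n1, n2) -> K (n1, n2, n3, n4).
    """
    if E_ket is None:
        E_ket = E_bra
    d = metric.solve(E_ket)
    return np.einsum("Aia,Ajb->iajb", E_bra, d, optimize=True)


def exact_eri_mo(ao_bra: AOBasis, Co_bra, Cv_bra,
                 ao_ket: AOBasis | None = None, Co_ket=None, Cv_ket=None,
                 eri_ao: np.ndarray | None = None) -> np.ndarray:
    """Exact MO-basis (ia|jb); the oracle for every fitted block."""
    if ao_ket is None:
        ao_ket, Co_ket, Cv_ket = ao_bra, Co_bra, Cv_bra
    if eri_ao is None:
        eri_ao = eri_coulomb(ao_bra, None if ao_ket is ao_bra else ao_ket)
    return np.einsum("mnls,mi,na,lj,sb->iajb", eri_ao, Co_bra, Cv_bra,
                     Co_ket, Cv_ket, optimize=True)


def orbital_centroids(ao: AOBasis, C: np.ndarray) -> np.ndarray:
    """<phi|r|phi> per MO column (needs normalised orbitals)."""
    X = ao.dipole()
    return np.stack([np.einsum("mi,mn,ni->i", C, X[k], C) for k in range(3)],
                    axis=1)


def screen_ep_three_index(E: np.ndarray, aux: AOBasis, centroids_occ,
                          centroids_virt, radius: float) -> np.ndarray:
    """Drop E(A'|ia) entries whose electronic pair charge centres both lie
    farther than ``radius`` (bohr) from the auxiliary centre.

    radius = inf keeps everything; radius = 0 keeps only on-centre entries.
    """
    if not np.isfinite(radius):
        return E
    out = E.copy()
    aux_atoms = aux.ao_atoms
    centers = np.array([c for c, _, _ in aux.entries])
    # per-aux-function center
    aux_centers = np.empty((aux.nbf, 3))
    for (c, s, _), off in zip(aux.entries, aux.offsets):
        aux_centers[off:off + 2 * s.l + 1] = c
    di = np.linalg.norm(centroids_occ[None, :, :] - aux_centers[:, None, :], axis=2)
    da = np.linalg.norm(centroids_virt[None, :, :] - aux_centers[:, None, :], axis=2)
    keep = (di[:, :, None] <= radius + 1e-12) & (da[:, None, :] <= radius + 1e-12)
    out[~keep] = 0.0
    return out
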