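"""NEO restricted Hartree-Fock: closed-shell electrons plus high-spin quantum
protons coupled through mean-field Coulomb terms.

The electronic subsystem is a conventional RHF problem in the field of the
classical point charges and the quantum-proton density; the nuclear subsystem
is a high-spin Hartree-Fock problem for distinguishable-spin... rather,
identical fermionic protons sharing one spin channel (singly occupied
orbitals, full same-spin exchange), with the proton kinetic energy scaled by
1/m_p.  The two sub-problems are interleaved: electrons are converged at
fixed proton density, then protons at fixed electronic density, until the
total energy is stationary.  DIIS accelerates each sub-SCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .basis import shells_for
from .constants import PROTON_MASS
from .integrals import AOBasis, eri_coulomb
from .system import SystemModel


class SCFConvergenceError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class ConvergenceSettings:
    """Sub-iteration thresholds are in au; the overall threshold in hartree."""

    sub_energy: float = 1e-8
    sub_density: float = 1e-8
    sub_gradient: float = 1e-8
    overall_energy: float = 1e-7
    diis_start: int = 2
    diis_size: int = 10
    max_sub_iter: int = 120
    max_outer_iter: int = 60

    def __post_init__(self):
        for name in ("sub_energy", "sub_density", "sub_gradient", "overall_energy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.diis_size < 2:
            raise ValueError("DIIS subspace size must be >= 2")


@dataclass
class SCFState:
    """Converged NEO-HF reference: MO coefficients and orbital energies for
    both particle types, the total energy, and the convergence history."""

    C_e: np.ndarray
    eps_e: np.ndarray
    C_p: np.ndarray | None
    eps_p: np.ndarray | None
    n_occ_e: int
    n_occ_p: int
    energy: float
    energy_terms: dict
    history: list
    model: SystemModel
    integrals: "NEOIntegrals"

    @property
    def C_occ_e(self):
        return self.C_e[:, : self.n_occ_e]

    @property
    def C_virt_e(self):
        return self.C_e[:, self.n_occ_e:]

    @property
    def C_occ_p(self):
        return None if self.C_p is None else self.C_p[:, : self.n_occ_p]

    @property
    def C_virt_p(self):
        return None if self.C_p is None else self.C_p[:, self.n_occ_p:]


class NEOIntegrals:
    """AO-basis integral store for one system: one-particle matrices and the
    exact two-particle tensors for the ee, pp and ep blocks (positive 1/r12
    kernel; charge signs are applied by consumers)."""

    def __init__(self, model: SystemModel):
        self.model = model
        e_entries = []
        for ia, atom in enumerate(model.atoms):
            for sh in shells_for(model.basis_electronic, atom.element):
                e_entries.append((atom.position, sh, ia))
        self.basis_e = AOBasis(e_entries)
        p_entries = []
        for ia, atom in enumerate(model.atoms):
            if atom.quantum:
                for sh in shells_for(model.basis_nuclear, "H"):
                    p_entries.append((atom.position, sh, ia))
        self.basis_p = AOBasis(p_entries) if p_entries else None

        classical = [(a.Z, np.asarray(a.position)) for a in model.classical_atoms]
        self.S_e = self.basis_e.overlap()
        self.T_e = self.basis_e.kinetic()
        self.V_e = self.basis_e.attraction([(-z, c) for z, c in classical]) \
            if classical else np.zeros_like(self.S_e)
        self.h_e = self.T_e + self.V_e
        self._eri_ee = None
        self._eri_pp = None
        self._eri_ep = None
        if self.basis_p is not None:
            self.S_p = self.basis_p.overlap()
            self.T_p = self.basis_p.kinetic() / PROTON_MASS
            self.V_p = self.basis_p.attraction([(+z, c) for z, c in classical]) \
                if classical else np.zeros((self.basis_p.nbf, self.basis_p.nbf))
            self.h_p = self.T_p + self.V_p
        # classical-classical point-charge repulsion
        enn = 0.0
        for i in range(len(classical)):
            for j in range(i + 1, len(classical)):
                zi, ci = classical[i]
                zj, cj = classical[j]
                enn += zi * zj / np.linalg.norm(ci - cj)
        self.E_nn = enn

    @property
    def eri_ee(self):
        if self._eri_ee is None:
            self._eri_ee = eri_coulomb(self.basis_e)
        return self._eri_ee

    @property
    def eri_pp(self):
        if self._eri_pp is None:
            self._eri_pp = eri_coulomb(self.basis_p)
        return self._eri_pp

    @property
    def eri_ep(self):
        """(mu nu | mu' nu') with electronic bra, nuclear ket; positive kernel."""
        if self._eri_ep is None:
            self._eri_ep = eri_coulomb(self.basis_e, self.basis_p)
        return self._eri_ep


def build_electronic_fock(ints: NEOIntegrals, P_e: np.ndarray,
                          P_p: np.ndarray | None) -> np.ndarray:
    """h_e + J[P_e] - K[P_e]/2 + attractive mean field of the proton density."""
    J = np.einsum("mnls,ls->mn", ints.eri_ee, P_e, optimize=True)
    K = np.einsum("mlns,ls->mn", ints.eri_ee, P_e, optimize=True)
    F = ints.h_e + J - 0.5 * K
    if P_p is not None and ints.basis_p is not None:
        F = F - np.einsum("mnab,ab->mn", ints.eri_ep, P_p, optimize=True)
    return F


def build_nuclear_fock(ints: NEOIntegrals, P_p: np.ndarray,
                       P_e: np.ndarray) -> np.ndarray:
    """h_p + (J - K)[P_p] over same-spin protons - repulsion... attraction to
    the electron density (sign: proton charge +1, electron charge -1)."""
    J = np.einsum("mnls,ls->mn", ints.eri_pp, P_p, optimize=True)
    K = np.einsum("mlns,ls->mn", ints.eri_pp, P_p, optimize=True)
    F = ints.h_p + J - K
    F = F - np.einsum("abmn,ab->mn", ints.eri_ep, P_e, optimize=True)
    return F


def total_energy(ints: NEOIntegrals, P_e, P_p) -> tuple[float, dict]:
    Je = np.einsum("mnls,ls->mn", ints.eri_ee, P_e, optimize=True)
    Ke = np.einsum("mlns,ls->mn", ints.eri_ee, P_e, optimize=True)
    terms = {
        "E_e_core": float(np.einsum("mn,mn->", P_e, ints.h_e)),
        "E_ee_mf": float(0.5 * np.einsum("mn,mn->", P_e, Je - 0.5 * Ke)),
        "E_nn_classical": ints.E_nn,
    }
    if P_p is not None:
        Jp = np.einsum("mnls,ls->mn", ints.eri_pp, P_p, optimize=True)
        Kp = np.einsum("mlns,ls->mn", ints.eri_pp, P_p, optimize=True)
        terms["E_p_core"] = float(np.einsum("mn,mn->", P_p, ints.h_p))
        terms["E_pp_mf"] = float(0.5 * np.einsum("mn,mn->", P_p, Jp - Kp))
        terms["E_ep_mf"] = float(-np.einsum("mnab,mn,ab->", ints.eri_ep,
                                            P_e, P_p, optimize=True))
    return sum(terms.values()), terms


class _DIIS:
    def __init__(self, size):
        self.size = size
        self.F = []
        self.err = []

    def push(self, F, err):
        self.F.append(F.copy())
        self.err.append(err.ravel().copy())
        if len(self.F) > self.size:
            self.F.pop(0)
            self.err.pop(0)

    def extrapolate(self):
        n = len(self.F)
        if n < 2:
            return self.F[-1]
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = self.err[i] @ self.err[j]
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return self.F[-1]
        return sum(ci * Fi for ci, Fi in zip(c, self.F))


def _sub_scf(h_builder, S, nocc, occ_number, P0, settings, label, history):
    """Converge one subsystem at fixed partner density.  Returns C, eps, P."""
    X = sla.fractional_matrix_power(S, -0.5)
    P = P0.copy()
    diis = _DIIS(settings.diis_size)
    e_old = None
    C = eps = None
    for it in range(1, settings.max_sub_iter + 1):
        F = h_builder(P)
        err = X.T @ (F @ P @ S - S @ P @ F) @ X
        if it >= settings.diis_start:
            diis.push(F, err)
            F = diis.extrapolate()
        eps, C = sla.eigh(F, S)
        Cocc = C[:, :nocc]
        P_new = occ_number * (Cocc @ Cocc.T)
        dP = np.abs(P_new - P).max()
        grad = np.abs(err).max()
        history.append({"subsystem": label, "iter": it, "grad": grad, "dP": dP})
        P = P_new
        if dP < settings.sub_density and grad < settings.sub_gradient:
            return C, eps, P
    raise SCFConvergenceError(f"{label} sub-SCF failed to converge "
                              f"in {settings.max_sub_iter} iterations", history)


def run_neo_scf(model: SystemModel, settings: ConvergenceSettings | None = None,
                ints: NEOIntegrals | None = None) -> SCFState:
    """Converge the NEO-HF reference (plain RHF when no nucleus is quantum)."""
    settings = settings or ConvergenceSettings()
    ints = ints or NEOIntegrals(model)
    nocc_e, nocc_p = model.n_electrons // 2, model.n_quantum_protons
    if model.n_electrons % 2:
        raise ValueError("open-shell electron counts are unsupported")

    history: list = []
    # initial guesses: electrons from a clamped-proton RHF (quantum protons as
    # point charges), then the proton from its Fock operator in that electron
    # density.  Starting from the classical-nuclei solution funnels the
    # interleaved SCF to the physical joint minimum; diffuse-dominated guesses
    # (e.g. bare kinetic eigenvectors) can trap it in spurious states.
    eps, C = sla.eigh(ints.h_e, ints.S_e)
    P_e = 2.0 * C[:, :nocc_e] @ C[:, :nocc_e].T
    if nocc_p > 0:
        V_clamp = ints.basis_e.attraction(
            [(-1.0, a.position) for a in model.quantum_atoms])
        C, _, P_e = _sub_scf(
            lambda P: build_electronic_fock(ints, P, None) + V_clamp,
            ints.S_e, nocc_e, 2.0, P_e, settings, "electronic-guess", history)
        h_guess = ints.h_p - np.einsum("abmn,ab->mn", ints.eri_ep, P_e,
                                       optimize=True)
        # site-local aufbau: one proton orbital per quantum centre (a global
        # aufbau can double-occupy the deepest well and start charge sloshing
        # between proton sites)
        ao_sites = ints.basis_p.ao_atoms
        P_p = np.zeros_like(ints.S_p)
        for site in sorted(set(ao_sites)):
            mask = ao_sites == site
            hb = h_guess[np.ix_(mask, mask)]
            sb = ints.S_p[np.ix_(mask, mask)]
            _, cb = sla.eigh(hb, sb)
            c = np.zeros(ints.S_p.shape[0])
            c[mask] = cb[:, 0]
            P_p += np.outer(c, c)
    else:
        P_p = None

    E_old, terms = total_energy(ints, P_e, P_p)
    C_e = eps_e = C_p = eps_p = None
    for outer in range(1, settings.max_outer_iter + 1):
        C_e, eps_e, P_e = _sub_scf(
            lambda P: build_electronic_fock(ints, P, P_p),
            ints.S_e, nocc_e, 2.0, P_e, settings, "electronic", history)
        if nocc_p > 0:
            C_p, eps_p, P_p = _sub_scf(
                lambda P: build_nuclear_fock(ints, P, P_e),
                ints.S_p, nocc_p, 1.0, P_p, settings, "nuclear", history)
        E, terms = total_energy(ints, P_e, P_p)
        # cross-consistency: electronic Brillouin gradient at the *updated*
        # proton density, so the converged state satisfies both subsystems
        if nocc_p > 0:
            F_cross = build_electronic_fock(ints, P_e, P_p)
            Xg = sla.fractional_matrix_power(ints.S_e, -0.5)
            cross = float(np.abs(
                Xg.T @ (F_cross @ P_e @ ints.S_e
                        - ints.S_e @ P_e @ F_cross) @ Xg).max())
        else:
            cross = 0.0
        history.append({"subsystem": "outer", "iter": outer,
                        "energy": E, "dE": E - E_old, "cross_grad": cross})
        if E - E_old > 1.0:
            raise SCFConvergenceError(
                f"NEO-SCF divergence: energy rose by {E - E_old:.3f} hartree",
                history)
        if abs(E - E_old) < settings.overall_energy and \
                cross < 10.0 * settings.sub_gradient:
            E_old = E
            break
        E_old = E
        if nocc_p == 0:
            break
    else:
        raise SCFConvergenceError("NEO-SCF outer loop failed to converge", history)

    return SCFState(C_e=C_e, eps_e=eps_e, C_p=C_p, eps_p=eps_p,
                    n_occ_e=nocc_e, n_occ_p=nocc_p, energy=E_old,
                    energy_terms=terms, history=history, model=model,
                    integrals=ints)
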