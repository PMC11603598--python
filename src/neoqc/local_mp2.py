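"""PNO-based local MP2 for the electron-electron channel.

Pipeline: localize the occupied electronic orbitals (Pipek-Mezey or
Foster-Boys Jacobi sweeps), screen occupied pairs by a semicanonical pair
energy estimate against the close/weak/distant/very-distant thresholds, build
pair natural orbitals by diagonalizing approximate external pair densities
from first-order semicanonical amplitudes, truncate each pair's virtual space
by occupation number and recovered pair-energy fraction, and solve the LMP2
amplitude equations iteratively (the occupied Fock block is non-diagonal in
localized orbitals).  Nuclear channels stay canonical; the assembler combines
the local ee energy with canonical ep/pp.

The domain hierarchy is deliberately simple: PNOs are built in the full
canonical virtual space per pair (no PAO/OSV cascade, no multipole treatment
of distant pairs); very-distant and discarded pairs contribute zero but their
estimated energies are reported as a dropped-energy bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mp2 import CorrelationResult


class LocalizationError(RuntimeError):
    pass


class LMP2ConvergenceError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class PairThresholds:
    """Pair-class energy thresholds (hartree) and PNO domain settings."""

    close: float = 1e-4
    weak: float = 1e-5
    distant: float = 1e-6
    very_distant: float = 1e-7
    pno_occupation: float = 1e-8
    pno_energy_fraction: float = 0.997

    def __post_init__(self):
        if not (self.close >= self.weak >= self.distant >= self.very_distant):
            raise ValueError("pair thresholds must be ordered "
                             "close >= weak >= distant >= very_distant")


@dataclass
class PairRecord:
    i: int
    j: int
    cls: str                      # close | weak | distant | very-distant | discarded
    estimate: float               # semicanonical pair energy estimate (hartree)
    energy: float = 0.0           # converged pair energy
    n_pno: int = 0

    @property
    def kept(self) -> bool:
        return self.cls in ("close", "weak", "distant")


@dataclass
class PNODomain:
    i: int
    j: int
    coefs: np.ndarray             # (n_virt, n_pno) over canonical virtuals
    occupations: np.ndarray       # descending, >= 0
    semicanonical_energy: float


@dataclass
class LocalOrbitalSet:
    C_loc: np.ndarray             # AO x nocc localized occupied coefficients
    U: np.ndarray                 # canonical -> localized rotation (nocc x nocc)
    method: str
    functional_value: float
    sweep_values: list = field(default_factory=list)


# ------------------------------------------------------------ localization

def _jacobi_localize(C, metric_fn, max_sweeps=200, tol=1e-10):
    """Generic 2x2 Jacobi sweep maximizing sum_A Q_A(i)^2-type functionals.

    ``metric_fn(C) -> Q`` with Q[A, i, j] the symmetrized atomic (or dipole
    component) matrix elements between orbitals i and j.
    """
    C = C.copy()
    n = C.shape[1]
    U = np.eye(n)
    values = []
    for sweep in range(max_sweeps):
        Q = metric_fn(C)
        values.append(float(np.sum(Q[:, range(n), range(n)] ** 2)))
        shift = 0.0
        for s in range(n - 1):
            for t in range(s + 1, n):
                Qst = Q[:, s, t]
                Qss = Q[:, s, s]
                Qtt = Q[:, t, t]
                A = float(np.sum(Qst ** 2 - 0.25 * (Qss - Qtt) ** 2))
                B = float(np.sum(Qst * (Qss - Qtt)))
                gain = A + np.hypot(A, B)
                if gain < 1e-14:
                    continue
                gamma = 0.25 * np.arctan2(B, -A)
                c, si = np.cos(gamma), np.sin(gamma)
                cs, cn = C[:, s].copy(), C[:, t].copy()
                C[:, s] = c * cs + si * cn
                C[:, t] = -si * cs + c * cn
                us, un = U[:, s].copy(), U[:, t].copy()
                U[:, s] = c * us + si * un
                U[:, t] = -si * us + c * un
                shift = max(shift, abs(si))
                Q = metric_fn(C)
        if shift < tol:
            Qf = metric_fn(C)
            values.append(float(np.sum(Qf[:, range(n), range(n)] ** 2)))
            return C, U, values
    raise LocalizationError(f"Jacobi sweeps did not settle in {max_sweeps} sweeps")


def localize_occupied(scf_state, method: str = "pipek-mezey",
                      max_sweeps: int = 200) -> LocalOrbitalSet:
    """Unitary localization of the occupied electronic orbitals.

    ``pipek-mezey`` maximizes the sum of squared Mulliken atomic charges;
    ``foster-boys`` maximizes the spread of orbital centroids (equivalently
    the sum of squared dipole matrix elements).  Deterministic: canonical
    orbital ordering seeds the sweeps.
    """
    C = scf_state.C_occ_e.copy()
    nocc = C.shape[1]
    key = method.lower().replace("_", "-")
    if key not in ("pipek-mezey", "pm", "foster-boys", "fb", "boys"):
        raise LocalizationError(
            f"unknown localizer {method!r}; available: pipek-mezey, foster-boys")
    if nocc == 1:
        return LocalOrbitalSet(C_loc=C, U=np.eye(1), method=key,
                               functional_value=1.0)
    ao = scf_state.integrals.basis_e
    S = scf_state.integrals.S_e
    if key in ("pipek-mezey", "pm"):
        atoms = ao.ao_atoms
        natom = atoms.max() + 1
        masks = [atoms == A for A in range(natom)]

        def metric(Cc):
            SC = S @ Cc
            Q = np.empty((natom, Cc.shape[1], Cc.shape[1]))
            for A, mask in enumerate(masks):
                M = Cc[mask].T @ SC[mask]
                Q[A] = 0.5 * (M + M.T)
            return Q
    elif key in ("foster-boys", "fb", "boys"):
        D = ao.dipole()

        def metric(Cc):
            return np.stack([Cc.T @ D[k] @ Cc for k in range(3)])
    else:
        raise LocalizationError(
            f"unknown localizer {method!r}; available: pipek-mezey, foster-boys")
    C_loc, U, values = _jacobi_localize(C, metric, max_sweeps=max_sweeps)
    return LocalOrbitalSet(C_loc=C_loc, U=U, method=key,
                           functional_value=values[-1], sweep_values=values)


# ---------------------------------------------------------- pair machinery

def _semicanonical_data(E3, F_occ, eps_virt):
    """Per-pair K matrices, first-order amplitudes and pair energies.

    E3: (naux, nocc, nvirt) fitted three-index tensor in the LMO basis.
    Returns dict[(i, j)] -> (K, T0, e_pair) for i <= j.
    """
    nocc = E3.shape[1]
    out = {}
    f_ii = np.diag(F_occ)
    for i in range(nocc):
        for j in range(i, nocc):
            K = np.einsum("Aa,Ab->ab", E3[:, i, :], E3[:, j, :])
            D = f_ii[i] + f_ii[j] - eps_virt[:, None] - eps_virt[None, :]
            T0 = K / D
            e = float(np.sum(T0 * (2.0 * K - K.T)) * (2.0 if i != j else 1.0))
            out[(i, j)] = (K, T0, e)
    return out


def screen_pairs(semican, thresholds: PairThresholds) -> list[PairRecord]:
    """Class every occupied pair by its semicanonical energy estimate."""
    records = []
    for (i, j), (_, _, e) in sorted(semican.items()):
        a = abs(e)
        if a >= thresholds.close:
            cls = "close"
        elif a >= thresholds.weak:
            cls = "weak"
        elif a >= thresholds.distant:
            cls = "distant"
        elif a >= thresholds.very_distant:
            cls = "very-distant"
        else:
            cls = "discarded"
        records.append(PairRecord(i=i, j=j, cls=cls, estimate=e))
    return records


def build_pnos(pair: tuple[int, int], K, T0, e_pair,
               thresholds: PairThresholds) -> PNODomain:
    """Diagonalize the approximate external pair density and truncate.

    Retained domain: every natural orbital with occupation >= the occupation
    threshold, plus enough further PNOs (by descending occupation) for the
    truncated semicanonical pair energy to reach the energy-fraction
    threshold.  Ties at exactly the occupation threshold are retained.
    """
    i, j = pair
    Tt = 2.0 * T0 - T0.T
    denom = 1.0 + (1.0 if i == j else 0.0)
    Dmat = (Tt @ T0.T + Tt.T @ T0) / denom
    occ, V = np.linalg.eigh(Dmat)
    order = np.argsort(occ)[::-1]
    occ = occ[order]
    V = V[:, order]
    occ = np.clip(occ, 0.0, None)
    nv = occ.size
    keep_occ = occ >= thresholds.pno_occupation
    n_min = int(np.count_nonzero(keep_occ))
    spin_fac = 2.0 if i != j else 1.0
    target = abs(e_pair) * thresholds.pno_energy_fraction
    n_keep = n_min
    for m in range(max(n_min, 1), nv + 1):
        d = V[:, :m]
        Kt = d.T @ K @ d
        T0t = d.T @ T0 @ d
        et = float(np.sum(T0t * (2.0 * Kt - Kt.T)) * spin_fac)
        n_keep = m
        if abs(et) >= target:
            break
    return PNODomain(i=i, j=j, coefs=V[:, :n_keep], occupations=occ[:n_keep],
                     semicanonical_energy=e_pair)


def solve_lmp2(records, domains, semican, F_occ, eps_virt,
               r_conv: float = 1e-7, max_iter: int = 200):
    """Iterative LMP2 amplitudes in the truncated PNO bases.

    Residual for pair (i, j) with amplitudes in the pair's PNO basis:
    R = K + F_vv T + T F_vv - sum_k [F_ik (S T^kj S) + F_kj (S T^ik S)],
    projected through the PNO overlaps S between pair domains.  Jacobi
    updates with the domain-diagonal denominators.
    """
    kept = [r for r in records if r.kept]
    pairs = [(r.i, r.j) for r in kept]
    pset = {p: k for k, p in enumerate(pairs)}
    f_ii = np.diag(F_occ)
    Kd, Fv, T = {}, {}, {}
    for p in pairs:
        d = domains[p].coefs
        K = semican[p][0]
        Kd[p] = d.T @ K @ d
        Fv[p] = d.T @ (np.diag(eps_virt)) @ d
        D = (f_ii[p[0]] + f_ii[p[1]]
             - np.diag(Fv[p])[:, None] - np.diag(Fv[p])[None, :])
        T[p] = Kd[p] / D

    def get_T(i, j):
        if i <= j:
            return T[(i, j)], domains[(i, j)].coefs
        t, d = T[(j, i)], domains[(j, i)].coefs
        return t.T, d

    nocc = F_occ.shape[0]
    history = []
    for it in range(1, max_iter + 1):
        rmax = 0.0
        T_new = {}
        for p in pairs:
            i, j = p
            dij = domains[p].coefs
            R = Kd[p] + Fv[p] @ T[p] + T[p] @ Fv[p]
            for k in range(nocc):
                if abs(F_occ[i, k]) > 1e-14 and (min(k, j), max(k, j)) in pset:
                    Tkj, dkj = get_T(k, j)
                    Skj = dij.T @ dkj
                    R -= F_occ[i, k] * (Skj @ Tkj @ Skj.T)
                if abs(F_occ[k, j]) > 1e-14 and (min(i, k), max(i, k)) in pset:
                    Tik, dik = get_T(i, k)
                    Sik = dij.T @ dik
                    R -= F_occ[k, j] * (Sik @ Tik @ Sik.T)
            # dR/dT diagonal is (F_aa + F_bb - F_ii - F_jj) = -D
            D = (f_ii[i] + f_ii[j]
                 - np.diag(Fv[p])[:, None] - np.diag(Fv[p])[None, :])
            T_new[p] = T[p] + R / D
            rmax = max(rmax, float(np.abs(R).max()))
        T = T_new
        history.append(rmax)
        if rmax < r_conv:
            break
    else:
        raise LMP2ConvergenceError(
            f"LMP2 residuals stalled at {history[-1]:.2e}", history)

    E = 0.0
    for rec in kept:
        p = (rec.i, rec.j)
        t = T[p]
        e = float(np.sum(t * (2.0 * Kd[p] - Kd[p].T))
                  * (2.0 if rec.i != rec.j else 1.0))
        rec.energy = e
        rec.n_pno = domains[p].coefs.shape[1]
        E += e
    dropped = sum(abs(r.estimate) for r in records if not r.kept)
    return E, {"iterations": len(history), "residual": history[-1],
               "dropped_estimate": dropped}


def pno_lmp2_ee(scf_state, E3_builder, thresholds: PairThresholds | None = None,
                localizer: str = "pipek-mezey", r_conv: float = 1e-7):
    """Full local-ee pipeline.

    ``E3_builder(C_occ_loc)`` must return the fitted three-index tensor
    (naux, nocc, nvirt) over localized occupied and canonical virtual
    orbitals.  Returns (energy, records, domains, info, lmos).
    """
    thresholds = thresholds or PairThresholds()
    lmos = localize_occupied(scf_state, method=localizer)
    eps_virt = scf_state.eps_e[scf_state.n_occ_e:]
    F_occ = lmos.U.T @ np.diag(scf_state.eps_e[: scf_state.n_occ_e]) @ lmos.U
    E3 = E3_builder(lmos.C_loc)
    semican = _semicanonical_data(E3, F_occ, eps_virt)
    records = screen_pairs(semican, thresholds)
    domains = {}
    for r in records:
        if r.kept:
            p = (r.i, r.j)
            K, T0, e = semican[p]
            domains[p] = build_pnos(p, K, T0, e, thresholds)
    energy, info = solve_lmp2(records, domains, semican, F_occ, eps_virt,
                              r_conv=r_conv)
    return energy, records, domains, info, lmos


def assemble_neo_pno_lmp2(E_ee_local: float, canonical: CorrelationResult,
                          records=None, info=None) -> CorrelationResult:
    """NEO-PNO-LMP2 total: local ee + canonical ep + canonical pp."""
    meta = dict(canonical.metadata)
    meta["route"] = "pno-lmp2"
    if info:
        meta.update({f"lmp2_{k}": v for k, v in info.items()})
    if records is not None:
        meta["n_pairs_kept"] = sum(r.kept for r in records)
        meta["n_pairs_total"] = len(records)
    return CorrelationResult(E_ee=E_ee_local, E_ep=canonical.E_ep,
                             E_pp=canonical.E_pp, metadata=meta)
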