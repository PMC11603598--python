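"""Drivers assembling NEO-MP2 channel energies from a converged reference.

Two integral routes feed the same channel formulas: the exact four-index
route (the comparison standard, size-guarded) and the density-fitted route
with the unified electronic+nuclear auxiliary basis for the ee/pp blocks and
the nuclear fitting set alone for the ep block.
"""

from __future__ import annotations

import numpy as np

from . import df as dfmod
from .integrals import AOBasis
from .mp2 import CorrelationResult, mp2_ee, mp2_ep, mp2_pp
from .scf import SCFState


def full_mo_eri(eri_ao: np.ndarray, C_bra: np.ndarray,
                C_ket: np.ndarray | None = None) -> np.ndarray:
    """All-orbital (pq|rs) from an AO tensor; ket defaults to the bra set."""
    if C_ket is None:
        C_ket = C_bra
    return np.einsum("mnls,mp,nq,lr,st->pqrt",
                     eri_ao, C_bra, C_bra, C_ket, C_ket, optimize=True)


def mo_blocks_exact(state: SCFState) -> dict:
    """Occ-virt MO integral blocks from the exact AO tensors.

    ``K_ep`` carries the attractive electron-proton sign.
    """
    ints = state.integrals
    out = {"K_ee": np.einsum("mnls,mi,na,lj,sb->iajb", ints.eri_ee,
                             state.C_occ_e, state.C_virt_e,
                             state.C_occ_e, state.C_virt_e, optimize=True)}
    if state.n_occ_p > 0:
        out["K_pp"] = np.einsum("mnls,mi,na,lj,sb->iajb", ints.eri_pp,
                                state.C_occ_p, state.C_virt_p,
                                state.C_occ_p, state.C_virt_p, optimize=True)
        out["K_ep"] = -np.einsum("mnls,mi,na,lj,sb->iajb", ints.eri_ep,
                                 state.C_occ_e, state.C_virt_e,
                                 state.C_occ_p, state.C_virt_p, optimize=True)
    return out


def channel_energies(state: SCFState, blocks: dict, meta=None) -> CorrelationResult:
    e_occ = state.eps_e[: state.n_occ_e]
    e_vir = state.eps_e[state.n_occ_e:]
    E_ee, pair = mp2_ee(blocks["K_ee"], e_occ, e_vir)
    res = CorrelationResult(E_ee=E_ee, pair_energies_ee=pair,
                            metadata=dict(meta or {}))
    if state.n_occ_p > 0:
        p_occ = state.eps_p[: state.n_occ_p]
        p_vir = state.eps_p[state.n_occ_p:]
        res.E_pp = mp2_pp(blocks["K_pp"], p_occ, p_vir)
        res.E_ep = mp2_ep(blocks["K_ep"], e_occ, e_vir, p_occ, p_vir)
    return res


def neo_mp2(state: SCFState) -> CorrelationResult:
    """Integral-direct (exact four-index) NEO-MP2."""
    return channel_energies(state, mo_blocks_exact(state),
                            meta={"route": "exact"})


def df_neo_mp2(state: SCFState, aux_electronic: str | None = None,
               aux_nuclear: str | None = None,
               ep_screen_radius: float = np.inf) -> CorrelationResult:
    """DF-NEO-MP2 with the unified auxiliary basis (ee, pp) and the nuclear
    fitting set for the ep block."""
    model = state.model
    ints = state.integrals
    aux_u = dfmod.unified_aux_basis(model, aux_electronic, aux_nuclear)
    metric_u = dfmod.compute_metric(aux_u)
    E_e = dfmod.compute_three_index(aux_u, ints.basis_e,
                                    state.C_occ_e, state.C_virt_e)
    blocks = {"K_ee": dfmod.fit_and_assemble(E_e, metric_u)}
    meta = {"route": "df", "aux_electronic": aux_electronic or model.aux_electronic,
            "aux_nuclear": aux_nuclear or model.aux_nuclear,
            "n_aux_unified": aux_u.nbf}
    if state.n_occ_p > 0:
        aux_n = dfmod.nuclear_aux_basis(model, aux_nuclear)
        metric_n = dfmod.compute_metric(aux_n)
        E_pp_u = dfmod.compute_three_index(aux_u, ints.basis_p,
                                           state.C_occ_p, state.C_virt_p)
        blocks["K_pp"] = dfmod.fit_and_assemble(E_pp_u, metric_u)
        E_e_n = dfmod.compute_three_index(aux_n, ints.basis_e,
                                          state.C_occ_e, state.C_virt_e)
        if np.isfinite(ep_screen_radius):
            co = dfmod.orbital_centroids(ints.basis_e, state.C_occ_e)
            cv = dfmod.orbital_centroids(ints.basis_e, state.C_virt_e)
            E_e_n = dfmod.screen_ep_three_index(E_e_n, aux_n, co, cv,
                                                ep_screen_radius)
        E_p_n = dfmod.compute_three_index(aux_n, ints.basis_p,
                                          state.C_occ_p, state.C_virt_p)
        blocks["K_ep"] = -dfmod.fit_and_assemble(E_e_n, metric_n, E_p_n)
        meta["n_aux_nuclear"] = aux_n.nbf
        meta["ep_screen_radius"] = ep_screen_radius
    return channel_energies(state, blocks, meta=meta)


def neo_pno_lmp2(state: SCFState, aux_electronic: str | None = None,
                 aux_nuclear: str | None = None, thresholds=None,
                 localizer: str = "pipek-mezey",
                 ep_screen_radius: float = np.inf, r_conv: float = 1e-7):
    """NEO-PNO-LMP2: local ee channel plus canonical DF ep/pp channels.

    Returns ``(CorrelationResult, pair_records, domains, solver_info)``.
    """
    from .local_mp2 import assemble_neo_pno_lmp2, pno_lmp2_ee

    model = state.model
    ints = state.integrals
    aux_u = dfmod.unified_aux_basis(model, aux_electronic, aux_nuclear)
    metric_u = dfmod.compute_metric(aux_u)

    def builder(C_occ_loc):
        E = dfmod.compute_three_index(aux_u, ints.basis_e, C_occ_loc,
                                      state.C_virt_e)
        return metric_u.half_solve(E)

    energy_ee, records, domains, info, _ = pno_lmp2_ee(
        state, builder, thresholds=thresholds, localizer=localizer,
        r_conv=r_conv)
    canonical = df_neo_mp2(state, aux_electronic, aux_nuclear,
                           ep_screen_radius=ep_screen_radius)
    res = assemble_neo_pno_lmp2(energy_ee, canonical, records, info)
    if canonical.E_ee != 0.0:
        res.metadata["ee_recovered_fraction"] = energy_ee / canonical.E_ee
    return res, records, domains, info
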