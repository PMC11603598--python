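"""Density fitting: metric conditioning, fitted blocks vs the exact oracle,
the unified auxiliary set and the nuclear-only ep fitting with screening."""

import warnings

import numpy as np
import pytest

from neoqc import df as dfmod
from neoqc.basis import Shell
from neoqc.constants import KCAL_PER_HARTREE
from neoqc.correlation import df_neo_mp2, neo_mp2
from neoqc.integrals import AOBasis
from neoqc.mp2 import mp2_ee
from neoqc.scf import run_neo_scf
from neoqc.system import generate_fixture

from conftest import strip_quantum


def _channel_errors(st, aux_e, aux_n):
    exact = neo_mp2(st)
    fitted = df_neo_mp2(st, aux_e, aux_n)
    return {ch: abs(getattr(fitted, ch) - getattr(exact, ch))
            for ch in ("E_ee", "E_ep", "E_pp")}, exact, fitted


def test_singular_metric_flagged_and_filtered():
    sh = Shell(0, [1.3], [1.0])
    aux = AOBasis([(np.zeros(3), sh, 0), (np.zeros(3), sh, 0)])
    with pytest.warns(RuntimeWarning, match="ill-conditioned"):
        metric = dfmod.compute_metric(aux)
    assert metric.is_singular
    # the filtered solve must still reproduce J d = E on the regular subspace
    E = np.array([[1.0], [1.0]])
    d = metric.solve(E)
    assert np.allclose(metric.J @ d, E, atol=1e-8)


def test_fit_error_decreases_tz_to_qz(st_water_1q):
    """Per-channel DF error cannot grow when the fitting chain is refined to
    its strict superset (the qz level)."""
    err_tz, _, _ = _channel_errors(st_water_1q, "autoaux-tz", "et-6s6p6d")
    err_qz, _, _ = _channel_errors(st_water_1q, "autoaux-qz",
                                   "et-10s10p10d10f")
    for ch in ("E_ee", "E_ep", "E_pp"):
        assert err_qz[ch] <= err_tz[ch] + 1e-12


def test_df_block_vs_exact_oracle_h2(st_h2_classical):
    """Fitted ee block against the exact 4-index oracle on H2."""
    st = st_h2_classical
    aux = dfmod.electronic_aux_basis(st.model, "autoaux-qz")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        metric = dfmod.compute_metric(aux)
        E3 = dfmod.compute_three_index(aux, st.integrals.basis_e,
                                       st.C_occ_e, st.C_virt_e)
        K_df = dfmod.fit_and_assemble(E3, metric)
    K_exact = dfmod.exact_eri_mo(st.integrals.basis_e, st.C_occ_e, st.C_virt_e,
                                 eri_ao=st.integrals.eri_ee)
    assert np.abs(K_df - K_exact).max() < 1e-4


def test_complete_fit_limit():
    """An auxiliary set spanning the orbital product space reproduces the
    exact integrals to solver tolerance (single-primitive s functions: the
    products are again s Gaussians on the same centre)."""
    sh = Shell(0, [0.8], [1.0])
    bas = AOBasis([(np.zeros(3), sh, 0)])
    aux = AOBasis([(np.zeros(3), Shell(0, [1.6], [1.0]), 0)])  # exact product
    from neoqc.integrals import eri_coulomb
    K_exact = eri_coulomb(bas)[0, 0, 0, 0]
    metric = dfmod.compute_metric(aux)
    E3 = dfmod.compute_three_index(aux, bas, np.eye(1), np.eye(1))
    K_df = dfmod.fit_and_assemble(E3, metric)[0, 0, 0, 0]
    assert K_df == pytest.approx(K_exact, abs=1e-12)


def test_unified_vs_electronic_only_ee(st_h2_1p):
    """Adding the far/compact nuclear fitting functions to the metric barely
    moves the fitted ee energy (tolerance, not identity)."""
    st = st_h2_1p
    ints = st.integrals
    e_occ, e_vir = st.eps_e[: st.n_occ_e], st.eps_e[st.n_occ_e:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aux_e = dfmod.electronic_aux_basis(st.model, "autoaux-tz")
        aux_u = dfmod.unified_aux_basis(st.model, "autoaux-tz", "et-6s6p6d")
        vals = []
        for aux in (aux_e, aux_u):
            metric = dfmod.compute_metric(aux)
            E3 = dfmod.compute_three_index(aux, ints.basis_e,
                                           st.C_occ_e, st.C_virt_e)
            K = dfmod.fit_and_assemble(E3, metric)
            vals.append(mp2_ee(K, e_occ, e_vir)[0])
    assert vals[0] == pytest.approx(vals[1], abs=1e-8)


def test_ep_screening_limits(st_h2_1p):
    st = st_h2_1p
    ints = st.integrals
    aux_n = dfmod.nuclear_aux_basis(st.model, "et-6s6p6d")
    E = dfmod.compute_three_index(aux_n, ints.basis_e, st.C_occ_e, st.C_virt_e)
    co = dfmod.orbital_centroids(ints.basis_e, st.C_occ_e)
    cv = dfmod.orbital_centroids(ints.basis_e, st.C_virt_e)
    unscreened = dfmod.screen_ep_three_index(E, aux_n, co, cv, np.inf)
    assert unscreened is E
    zero = dfmod.screen_ep_three_index(E, aux_n, co, cv, 0.0)
    assert np.abs(zero).sum() < np.abs(E).sum()


def test_ep_screening_default_radius_small_shift(st_water_1q):
    """With the default 5 a0 proximity radius the ep energy moves by less
    than 1e-6 hartree on a hydrogen-bond-scale system."""
    full = df_neo_mp2(st_water_1q, "autoaux-tz", "et-6s6p6d")
    scr = df_neo_mp2(st_water_1q, "autoaux-tz", "et-6s6p6d",
                     ep_screen_radius=5.0)
    assert abs(scr.E_ep - full.E_ep) < 1e-6


def test_df_error_trend_with_system_size():
    """Total DF error grows (weakly, near-linearly) with chain length."""
    errs = []
    for n in (1, 2, 3):
        m = strip_quantum(generate_fixture(f"water-chain({n})").with_basis(
            electronic="sto-3g"))
        st = run_neo_scf(m)
        exact = neo_mp2(st)
        fitted = df_neo_mp2(st, "autoaux-tz")
        errs.append(abs(fitted.E_ee - exact.E_ee))
    assert errs[0] <= errs[1] <= errs[2]
    # and stays at the sub-kcal/mol scale throughout
    assert errs[-1] * KCAL_PER_HARTREE < 0.1


def test_nuclear_only_aux_requires_quantum_protons(st_water_classical):
    with pytest.raises(ValueError, match="quantum protons"):
        dfmod.nuclear_aux_basis(st_water_classical.model)


def test_metric_positive_definite(st_h2_1p):
    aux = dfmod.nuclear_aux_basis(st_h2_1p.model, "et-6s6p6d")
    J = dfmod.compute_metric(aux).J
    assert np.allclose(J, J.T, atol=1e-12)
    assert np.linalg.eigvalsh(J).min() > 0
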