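"""NEO-HF reference: reduction limits, variational behaviour, invariances."""

from dataclasses import replace

import numpy as np
import pytest

from neoqc.constants import PROTON_MASS
from neoqc.scf import (ConvergenceSettings, NEOIntegrals, SCFConvergenceError,
                       build_electronic_fock, build_nuclear_fock, run_neo_scf)
from neoqc.system import AtomSpec, generate_fixture

from _reference import reference_rhf


def test_default_settings_reproduce_quoted_thresholds():
    s = ConvergenceSettings()
    assert s.sub_energy == s.sub_density == s.sub_gradient == 1e-8
    assert s.overall_energy == 1e-7
    assert s.diis_start == 2 and s.diis_size == 10


def test_invalid_settings_rejected():
    with pytest.raises(ValueError):
        ConvergenceSettings(sub_energy=0.0)
    with pytest.raises(ValueError):
        ConvergenceSettings(diis_size=1)


def test_zero_quantum_nuclei_matches_independent_rhf(st_water_classical):
    """With no quantum protons NEO-HF must reduce to conventional RHF; the
    reference is a standalone damped Roothaan iteration."""
    st = st_water_classical
    ints = st.integrals
    E_ref, eps_ref, _ = reference_rhf(ints.S_e, ints.h_e, ints.eri_ee,
                                      st.n_occ_e, e_nuc=ints.E_nn)
    assert st.energy == pytest.approx(E_ref, abs=1e-9)
    assert np.allclose(st.eps_e[: st.n_occ_e], eps_ref[: st.n_occ_e], atol=1e-6)


def test_h2_sto3g_literature_energy(st_h2_classical):
    # RHF/STO-3G H2 near equilibrium, textbook value
    assert st_h2_classical.energy == pytest.approx(-1.11668, abs=2e-4)


def test_neo_hf_above_classical_reference(st_h2_1p, st_h2_classical):
    """Quantizing a proton adds zero-point motion: the NEO-HF energy lies
    above the clamped-nucleus RHF energy at the same geometry."""
    assert st_h2_1p.energy > st_h2_classical.energy


def test_brillouin_condition(st_h2_1p):
    st = st_h2_1p
    ints = st.integrals
    P_e = 2.0 * st.C_occ_e @ st.C_occ_e.T
    P_p = st.C_occ_p @ st.C_occ_p.T
    F_e = build_electronic_fock(ints, P_e, P_p)
    F_p = build_nuclear_fock(ints, P_p, P_e)
    ov_e = st.C_occ_e.T @ F_e @ st.C_virt_e
    ov_p = st.C_occ_p.T @ F_p @ st.C_virt_p
    assert np.abs(ov_e).max() < 1e-6
    assert np.abs(ov_p).max() < 1e-6


def test_electronic_fock_reduces_to_rhf_without_protons(st_water_classical):
    st = st_water_classical
    ints = st.integrals
    P_e = 2.0 * st.C_occ_e @ st.C_occ_e.T
    F0 = build_electronic_fock(ints, P_e, None)
    J = np.einsum("mnls,ls->mn", ints.eri_ee, P_e)
    K = np.einsum("mlns,ls->mn", ints.eri_ee, P_e)
    assert np.allclose(F0, ints.h_e + J - 0.5 * K, atol=1e-13)


def test_ep_mean_field_attractive(st_h2_1p):
    st = st_h2_1p
    P_e = 2.0 * st.C_occ_e @ st.C_occ_e.T
    P_p = st.C_occ_p @ st.C_occ_p.T
    v_ep = -np.einsum("mnab,mn,ab->", st.integrals.eri_ep, P_e, P_p)
    assert v_ep < 0.0


def test_proton_kinetic_mass_scaling(st_h2_1p):
    ints = st_h2_1p.integrals
    raw = ints.basis_p.kinetic()
    assert np.allclose(ints.T_p, raw / PROTON_MASS, atol=1e-14)


def test_nuclear_basis_variational_monotonicity():
    """A superset protonic basis can only lower the NEO-HF energy."""
    small = generate_fixture("h2-oneproton").with_basis(
        electronic="sto-3g", nuclear="prot-1s")
    big = small.with_basis(nuclear="prot-sp")
    bigger = small.with_basis(nuclear="prot-spd")
    e = [run_neo_scf(m).energy for m in (small, big, bigger)]
    assert e[0] >= e[1] >= e[2]


def test_translation_invariance():
    m = generate_fixture("h2-oneproton").with_basis(electronic="sto-3g",
                                                    nuclear="prot-sp")
    e0 = run_neo_scf(m).energy
    shift = np.array([1.3, -0.7, 2.1])
    m2 = replace(m, atoms=tuple(
        AtomSpec(a.element, tuple(np.asarray(a.position) + shift), a.quantum)
        for a in m.atoms))
    e1 = run_neo_scf(m2).energy
    assert e1 == pytest.approx(e0, abs=1e-9)


def test_single_proton_high_spin_self_interaction_free(st_h2_1p):
    """One quantum proton: its mean-field pp energy vanishes (J = K)."""
    st = st_h2_1p
    P_p = st.C_occ_p @ st.C_occ_p.T
    Jp = np.einsum("mnls,ls->mn", st.integrals.eri_pp, P_p)
    Kp = np.einsum("mlns,ls->mn", st.integrals.eri_pp, P_p)
    assert 0.5 * np.sum(P_p * (Jp - Kp)) == pytest.approx(0.0, abs=1e-12)


def test_open_shell_rejected():
    m = generate_fixture("water").with_basis(electronic="sto-3g",
                                             nuclear="prot-sp")
    m_odd = replace(m, charge=1)    # 9 electrons
    with pytest.raises(ValueError):
        run_neo_scf(m_odd)


def test_nonconvergence_error_carries_history():
    m = generate_fixture("h2-oneproton").with_basis(electronic="sto-3g",
                                                    nuclear="prot-sp")
    tight = ConvergenceSettings(max_sub_iter=2)
    with pytest.raises(SCFConvergenceError) as err:
        run_neo_scf(m, tight)
    assert len(err.value.history) > 0
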