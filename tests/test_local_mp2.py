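"""Localization, pair screening, PNO truncation and the LMP2 solver.

The central correctness property is the zero-truncation limit: with every
threshold at zero the PNO-LMP2 ee energy must reproduce the canonical DF-MP2
ee energy, because MP2 is invariant under rotations within the occupied
space.
"""

import numpy as np
import pytest

from neoqc import df as dfmod
from neoqc.correlation import df_neo_mp2, neo_pno_lmp2
from neoqc.local_mp2 import (LocalizationError, PairThresholds, build_pnos,
                             localize_occupied, screen_pairs,
                             _semicanonical_data)
from neoqc.mp2 import mp2_ee
from neoqc.scf import run_neo_scf
from neoqc.system import generate_fixture, parse_xyz

from conftest import strip_quantum

ZERO = PairThresholds(close=0.0, weak=0.0, distant=0.0, very_distant=0.0,
                      pno_occupation=0.0, pno_energy_fraction=1.0)


def test_default_thresholds_reproduce_footnote_values():
    t = PairThresholds()
    assert (t.close, t.weak, t.distant, t.very_distant) == (1e-4, 1e-5, 1e-6, 1e-7)
    assert t.pno_occupation == 1e-8
    assert t.pno_energy_fraction == 0.997


def test_threshold_ordering_enforced():
    with pytest.raises(ValueError):
        PairThresholds(close=1e-6, weak=1e-4)


def test_localization_unitary_and_density_invariant(st_chain2_classical):
    st = st_chain2_classical
    S = st.integrals.S_e
    for method in ("pipek-mezey", "foster-boys"):
        loc = localize_occupied(st, method=method)
        # unitary w.r.t. the occupied space
        assert np.allclose(loc.U.T @ loc.U, np.eye(st.n_occ_e), atol=1e-10)
        assert np.allclose(loc.C_loc.T @ S @ loc.C_loc, np.eye(st.n_occ_e),
                           atol=1e-10)
        # the one-particle density (hence the HF energy) is untouched
        P0 = st.C_occ_e @ st.C_occ_e.T
        P1 = loc.C_loc @ loc.C_loc.T
        assert np.allclose(P0, P1, atol=1e-10)


def test_pm_functional_nondecreasing_over_sweeps(st_chain2_classical):
    loc = localize_occupied(st_chain2_classical, method="pipek-mezey")
    vals = np.array(loc.sweep_values)
    assert np.all(np.diff(vals) > -1e-10)
    assert loc.functional_value >= vals[0]


def test_single_occupied_orbital_unchanged(st_h2_classical):
    loc = localize_occupied(st_h2_classical)
    assert np.allclose(np.abs(loc.U), np.eye(1), atol=1e-12)


def test_unknown_localizer_rejected(st_h2_classical):
    with pytest.raises(LocalizationError):
        localize_occupied(st_h2_classical, method="magic")


def _semican(st, aux_name="autoaux-tz"):
    aux = dfmod.electronic_aux_basis(st.model, aux_name)
    metric = dfmod.compute_metric(aux)
    loc = localize_occupied(st)
    E = dfmod.compute_three_index(aux, st.integrals.basis_e, loc.C_loc,
                                  st.C_virt_e)
    B = metric.half_solve(E)
    F_occ = loc.U.T @ np.diag(st.eps_e[: st.n_occ_e]) @ loc.U
    eps_virt = st.eps_e[st.n_occ_e:]
    return _semicanonical_data(B, F_occ, eps_virt), F_occ, eps_virt


def test_zero_thresholds_class_everything_close(st_chain2_classical):
    semican, _, _ = _semican(st_chain2_classical)
    records = screen_pairs(semican, ZERO)
    assert all(r.cls == "close" for r in records)
    nocc = st_chain2_classical.n_occ_e
    assert len(records) == nocc * (nocc + 1) // 2


def test_distant_fragments_screened_out():
    """Two waters 100 A apart: every inter-fragment pair falls below the
    very-distant threshold."""
    text = ["6", "far dimer"]
    from neoqc.system import generate_fixture
    for shift in (0.0, 100.0):
        w = generate_fixture("water")
        for a in w.atoms:
            p = np.asarray(a.position) * 0.529177210903
            text.append(f"{a.element} {p[0] + shift:.6f} {p[1]:.6f} {p[2]:.6f}")
    m = strip_quantum(parse_xyz("\n".join(text)).with_basis(electronic="sto-3g"))
    st = run_neo_scf(m)
    semican, _, _ = _semican(st)
    records = screen_pairs(semican, PairThresholds())
    loc = localize_occupied(st)
    # identify fragments by localized centroids
    D = st.integrals.basis_e.dipole()
    cx = np.array([loc.C_loc[:, i] @ D[0] @ loc.C_loc[:, i]
                   for i in range(st.n_occ_e)])
    frag = cx > 50.0
    for r in records:
        if frag[r.i] != frag[r.j]:
            assert r.cls == "discarded"
            assert abs(r.estimate) < 1e-7


def test_pno_occupations_descending_nonnegative(st_chain2_classical):
    semican, _, _ = _semican(st_chain2_classical)
    p = (0, 1)
    K, T0, e = semican[p]
    dom = build_pnos(p, K, T0, e, PairThresholds())
    assert np.all(dom.occupations >= 0)
    assert np.all(np.diff(dom.occupations) <= 1e-14)


def test_pno_no_truncation_keeps_full_space(st_chain2_classical):
    semican, _, _ = _semican(st_chain2_classical)
    nvirt = st_chain2_classical.C_virt_e.shape[1]
    p = (0, 0)
    K, T0, e = semican[p]
    dom = build_pnos(p, K, T0, e, ZERO)
    assert dom.coefs.shape == (nvirt, nvirt)


def test_zero_truncation_recovers_canonical(st_chain2_classical):
    """Thresholds -> 0: PNO-LMP2 ee equals canonical DF-MP2 ee to solver
    tolerance (MP2 invariance under occupied rotations)."""
    st = st_chain2_classical
    canonical = df_neo_mp2(st, "autoaux-tz")
    res, records, domains, info = neo_pno_lmp2(st, "autoaux-tz",
                                               thresholds=ZERO, r_conv=1e-9)
    assert res.E_ee == pytest.approx(canonical.E_ee, abs=1e-8)
    assert all(r.cls == "close" for r in records)


def test_threshold_ladder_monotone_recovery(st_chain2_classical):
    """Tightening every threshold one decade never loses correlation."""
    st = st_chain2_classical
    canonical = df_neo_mp2(st, "autoaux-tz")
    fractions = []
    for scale, occ_thr, frac in ((1.0, 1e-6, 0.99), (0.1, 1e-7, 0.997),
                                 (0.01, 1e-8, 0.9995)):
        thr = PairThresholds(close=1e-4 * scale, weak=1e-5 * scale,
                             distant=1e-6 * scale, very_distant=1e-7 * scale,
                             pno_occupation=occ_thr,
                             pno_energy_fraction=frac)
        res, *_ = neo_pno_lmp2(st, "autoaux-tz", thresholds=thr)
        fractions.append(res.E_ee / canonical.E_ee)
    assert all(0.0 < f <= 1.0 + 1e-10 for f in fractions)
    assert fractions[0] <= fractions[1] + 1e-10 <= fractions[2] + 2e-10


def test_chain4_default_thresholds_accuracy(st_chain4_classical):
    """Defaults on the four-water chain: unaccounted ee correlation < 1%."""
    st = st_chain4_classical
    canonical = df_neo_mp2(st, "autoaux-tz")
    res, records, domains, info = neo_pno_lmp2(st, "autoaux-tz")
    unaccounted = 1.0 - res.E_ee / canonical.E_ee
    assert 0.0 <= unaccounted < 0.01
    assert info["dropped_estimate"] >= 0.0
    # the dropped-pair estimate bounds the observed loss to its order of magnitude
    loss = abs(canonical.E_ee - res.E_ee)
    assert loss < max(50.0 * info["dropped_estimate"], 0.01 * abs(canonical.E_ee))


def test_assembled_total_reports_channels(st_water_1q):
    res, records, domains, info = neo_pno_lmp2(st_water_1q, "autoaux-tz",
                                               aux_nuclear="et-6s6p6d")
    canonical = df_neo_mp2(st_water_1q, "autoaux-tz", "et-6s6p6d")
    assert res.E_ep == pytest.approx(canonical.E_ep, abs=1e-12)
    assert res.E_pp == pytest.approx(canonical.E_pp, abs=1e-12)
    assert res.total == pytest.approx(res.E_ee + res.E_ep + res.E_pp)
    assert "ee_recovered_fraction" in res.metadata
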