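"""Integral engine checks against literature values and analytic oracles."""

import math

import numpy as np
import pytest

from neoqc.basis import Shell, shells_for
from neoqc.integrals import (AOBasis, SizeGuardError, boys, eri_coulomb,
                             solid_harmonic_transform, three_center,
                             two_center, _check_size)


@pytest.fixture(scope="module")
def h2_sto3g():
    sh = shells_for("sto-3g", "H")[0]
    A, B = np.zeros(3), np.array([1.4, 0.0, 0.0])
    return AOBasis([(A, sh, 0), (B, sh, 1)])


def test_h2_sto3g_literature_values(h2_sto3g):
    """One- and two-electron H2/STO-3G integrals at R = 1.4 bohr (standard
    textbook tabulation)."""
    bas = h2_sto3g
    S = bas.overlap()
    T = bas.kinetic()
    V = bas.attraction([(-1.0, np.zeros(3)), (-1.0, np.array([1.4, 0, 0]))])
    assert S[0, 0] == pytest.approx(1.0, abs=1e-12)
    assert S[0, 1] == pytest.approx(0.6593, abs=2e-4)
    assert T[0, 0] == pytest.approx(0.7600, abs=2e-4)
    assert T[0, 1] == pytest.approx(0.2365, abs=2e-4)
    assert V[0, 0] == pytest.approx(-1.8804, abs=3e-4)
    eri = eri_coulomb(bas)
    assert eri[0, 0, 0, 0] == pytest.approx(0.7746, abs=2e-4)
    assert eri[0, 0, 1, 1] == pytest.approx(0.5697, abs=2e-4)
    assert eri[0, 1, 0, 1] == pytest.approx(0.2970, abs=2e-4)
    assert eri[0, 0, 0, 1] == pytest.approx(0.4441, abs=2e-4)


def test_eri_permutation_symmetry(h2_sto3g):
    eri = eri_coulomb(h2_sto3g)
    assert np.allclose(eri, eri.transpose(1, 0, 2, 3), atol=1e-14)
    assert np.allclose(eri, eri.transpose(0, 1, 3, 2), atol=1e-14)
    assert np.allclose(eri, eri.transpose(2, 3, 0, 1), atol=1e-14)


def test_metric_single_s_function_closed_form():
    """1x1 Coulomb metric vs an independent radial-quadrature evaluation."""
    a = 1.7
    aux = AOBasis([(np.zeros(3), Shell(0, [a], [1.0]), 0)])
    J = two_center(aux)[0, 0]
    r = np.linspace(1e-6, 12.0, 40001)
    f = (2 * a / np.pi) ** 0.75 * np.exp(-a * r ** 2)
    inner = np.array([np.trapezoid(r ** 2 * f / np.maximum(r, s), r) for s in r])
    quad = (4 * np.pi) ** 2 * np.trapezoid(r ** 2 * f * inner, r)
    assert J == pytest.approx(quad, abs=1e-6)


def test_metric_permutation_covariance():
    shells = [Shell(0, [0.8], [1.0]), Shell(0, [2.2], [1.0]), Shell(1, [1.1], [1.0])]
    c = [np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0])]
    aux = AOBasis([(c[k], shells[k], k) for k in range(3)])
    aux_perm = AOBasis([(c[k], shells[k], k) for k in (1, 0, 2)])
    J = two_center(aux)
    Jp = two_center(aux_perm)
    perm = [1, 0, 2, 3, 4]   # s, s swap; p block (3 funcs) trails
    assert np.allclose(Jp, J[np.ix_(perm, perm)], atol=1e-12)


def test_duplicated_aux_function_gives_singular_metric():
    sh = Shell(0, [1.3], [1.0])
    aux = AOBasis([(np.zeros(3), sh, 0), (np.zeros(3), sh, 0)])
    J = two_center(aux)
    assert np.linalg.eigvalsh(J)[0] == pytest.approx(0.0, abs=1e-10)


def test_three_center_limit_of_four_center():
    """(A|mu nu) equals lim (A d_eps|mu nu)/N_eps for a wide s partner d_eps:
    an independent route through the generic four-centre code."""
    shH = shells_for("sto-3g", "H")[0]
    bas = AOBasis([(np.zeros(3), shH, 0), (np.array([1.4, 0, 0]), shH, 1)])
    aux_shell = Shell(1, [0.9], [1.0])
    caux = np.array([0.7, 0.2, 0.0])
    aux = AOBasis([(caux, aux_shell, 0)])
    E = three_center(aux, bas)

    eps = 1e-7
    wide = Shell(0, [eps], [1.0])
    bra = AOBasis([(caux, aux_shell, 0), (caux, wide, 0)])
    eri = eri_coulomb(bra, bas)
    n_eps = (2 * eps / np.pi) ** 0.75
    approx = eri[:3, 3, :, :] / n_eps
    assert np.allclose(E, approx, rtol=1e-4, atol=1e-9)


def test_solid_harmonic_d_shell_rows():
    T = solid_harmonic_transform(2)
    comps = [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)]
    # m = -2 -> xy, m = -1 -> yz, m = 0 -> z^2 - (x^2+y^2)/2, m=1 -> xz, m=2 -> (x^2-y^2)
    def row(m):
        return {c: T[2 + m, k] for k, c in enumerate(comps) if T[2 + m, k] != 0}
    assert row(-2) == {(1, 1, 0): pytest.approx(2.0)}
    assert row(-1) == {(0, 1, 1): pytest.approx(2.0)}
    assert row(0) == {(2, 0, 0): pytest.approx(-0.5), (0, 2, 0): pytest.approx(-0.5),
                      (0, 0, 2): pytest.approx(1.0)}
    assert row(1) == {(1, 0, 1): pytest.approx(2.0)}
    assert row(2) == {(2, 0, 0): pytest.approx(1.0), (0, 2, 0): pytest.approx(-1.0)}


def test_boys_small_and_large_arguments():
    x = np.array([0.0, 1e-14, 0.5, 5.0, 30.0])
    F = boys(4, x)
    assert F[0, 0] == pytest.approx(1.0)
    assert F[2, 0] == pytest.approx(1.0 / 5.0)
    # large-x asymptote F0 ~ sqrt(pi/(4x))
    assert F[0, -1] == pytest.approx(math.sqrt(math.pi / (4 * 30.0)), rel=1e-6)
    assert np.all(np.diff(F[:, 2]) < 0)   # decreasing in order n


def test_ep_block_decays_with_distance():
    shH = shells_for("sto-3g", "H")[0]
    prot = Shell(0, [12.0], [1.0])
    near, far = [], []
    for d, store in ((2.0, near), (30.0, far)):
        e = AOBasis([(np.zeros(3), shH, 0)])
        p = AOBasis([(np.array([d, 0, 0]), prot, 0)])
        store.append(eri_coulomb(e, p)[0, 0, 0, 0])
    assert far[0] < near[0]
    assert far[0] == pytest.approx(1.0 / 30.0, rel=1e-3)  # point-charge limit


def test_size_guard_refuses_large_requests():
    with pytest.raises(SizeGuardError, match="exceeds"):
        _check_size([1000, 1000, 1000, 1000])


def test_dipole_matches_finite_difference_center():
    """<1s_A|x|1s_A> must equal the centre coordinate for a normalized s AO."""
    sh = Shell(0, [0.9], [1.0])
    c = np.array([0.3, -0.4, 1.1])
    bas = AOBasis([(c, sh, 0)])
    D = bas.dipole()
    assert np.allclose([D[k][0, 0] for k in range(3)], c, atol=1e-12)
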