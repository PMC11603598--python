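"""Shared fixtures: small converged NEO-HF references, built once per session.

All systems use compact test bases (STO-3G electrons, few-function protonic
sets) so the whole suite stays within desk-scale runtimes; the physics being
checked (channel formulas, fitting errors, localization, truncation limits)
is basis-size independent.
"""

from dataclasses import replace

import pytest

from neoqc.scf import run_neo_scf
from neoqc.system import AtomSpec, generate_fixture


def strip_quantum(model):
    return replace(model, atoms=tuple(
        AtomSpec(a.element, a.position, False) for a in model.atoms))


def _converge(name, electronic="sto-3g", nuclear="prot-sp", quantum=None):
    model = generate_fixture(name).with_basis(electronic=electronic,
                                              nuclear=nuclear)
    if quantum == "none":
        model = strip_quantum(model)
    elif quantum is not None:
        model = replace(model, atoms=tuple(
            AtomSpec(a.element, a.position, k in quantum)
            for k, a in enumerate(model.atoms)))
    return run_neo_scf(model)


@pytest.fixture(scope="session")
def st_h2_1p():
    return _converge("h2-oneproton")


@pytest.fixture(scope="session")
def st_h2_2p():
    return _converge("h2-twoproton")


@pytest.fixture(scope="session")
def st_h2_classical():
    return _converge("h2-oneproton", quantum="none")


@pytest.fixture(scope="session")
def st_water_1q():
    # water with the free (non-donor) hydrogen quantum
    return _converge("water", quantum={2})


@pytest.fixture(scope="session")
def st_water_classical():
    return _converge("water", quantum="none")


@pytest.fixture(scope="session")
def st_chain2_classical():
    return _converge("water-chain(2)", quantum="none")


@pytest.fixture(scope="session")
def st_chain4_classical():
    return _converge("water-chain(4)", quantum="none")


@pytest.fixture(scope="session")
def st_zundel():
    return _converge("zundel")
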