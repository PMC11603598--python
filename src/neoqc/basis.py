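"""Gaussian basis-set registry: shells, counting, and even-tempered generators.

Shells are spherical (a shell of angular momentum ``l`` carries ``2l+1``
functions).  Named sets are resolved from the packaged JSON library; three
families are generated programmatically:

* ``et-10s10p10d10f`` (and any ``et-<n>s<n>p...`` pattern) — even-tempered
  nuclear fitting sets with exponents spanning 2*sqrt(2) .. 64.  For the
  canonical 10-exponent set the ratio works out to sqrt(2), i.e.
  ``alpha_k = 2**((k+2)/2)``.
* ``autoaux-tz`` / ``autoaux-qz`` — even-tempered electronic fitting sets
  derived from the orbital basis of the element; the qz chain is a strict
  superset of the tz chain (denser spacing plus one extra angular momentum),
  so enlarging the fit set can only improve the fitted densities.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

L_LETTERS = "spdfghik"


class BasisError(KeyError):
    """Unknown basis name, element, or a counting-only set used for energies."""


@dataclass
class Shell:
    """One contracted spherical Gaussian shell.

    invariants: ``l >= 0``, all exponents positive, ``2l+1`` functions.
    """

    l: int
    exps: np.ndarray
    coefs: np.ndarray
    spherical: bool = True

    def __post_init__(self):
        self.exps = np.atleast_1d(np.asarray(self.exps, dtype=float))
        self.coefs = np.atleast_1d(np.asarray(self.coefs, dtype=float))
        if self.l < 0:
            raise ValueError("angular momentum must be >= 0")
        if np.any(self.exps <= 0):
            raise ValueError("shell exponents must be positive")
        if self.exps.shape != self.coefs.shape:
            raise ValueError("exponent/coefficient length mismatch")

    @property
    def nfunc(self) -> int:
        return 2 * self.l + 1

    @property
    def ncart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


@lru_cache(maxsize=1)
def _library() -> dict:
    with resources.files("neoqc.data").joinpath("basis_library.json").open() as fh:
        return json.load(fh)


def parse_composition(comp: str) -> list[tuple[int, int]]:
    """``"4s3p2d1f"`` -> ``[(0, 4), (1, 3), (2, 2), (3, 1)]``."""
    out = []
    for count, letter in re.findall(r"(\d+)([a-z])", comp):
        out.append((L_LETTERS.index(letter), int(count)))
    if not out:
        raise BasisError(f"cannot parse composition string {comp!r}")
    return out


def composition_nfunc(comp: str) -> int:
    return sum(n * (2 * l + 1) for l, n in parse_composition(comp))


_ET_PATTERN = re.compile(r"^et-((?:\d+[a-z])+)$")


def _even_tempered(alpha_lo: float, alpha_hi: float, n: int) -> np.ndarray:
    if n == 1:
        return np.array([math.sqrt(alpha_lo * alpha_hi)])
    beta = (alpha_hi / alpha_lo) ** (1.0 / (n - 1))
    return alpha_lo * beta ** np.arange(n)


def even_tempered_nuclear_shells(comp: str = "10s10p10d10f",
                                 alpha_lo: float = 2.0 * math.sqrt(2.0),
                                 alpha_hi: float = 64.0) -> list[Shell]:
    """Nuclear fitting shells with exponents shared across angular momenta."""
    shells = []
    for l, n in parse_composition(comp):
        exps = _even_tempered(alpha_lo, alpha_hi, n)
        for a in exps:
            shells.append(Shell(l, [a], [1.0]))
    return shells


def _uncontract(entries) -> list[Shell]:
    shells = []
    for e in entries:
        if e["coefs"] is None:
            for a in e["exps"]:
                shells.append(Shell(e["l"], [a], [1.0]))
        else:
            shells.append(Shell(e["l"], e["exps"], e["coefs"]))
    return shells


def autoaux_shells(orbital_basis: str, element: str, level: str = "tz") -> list[Shell]:
    """Even-tempered fitting set derived from an element's orbital basis.

    The ``qz`` set is a strict superset of ``tz``: same chains plus geometric
    midpoints and one higher angular momentum.
    """
    if level not in ("tz", "qz"):
        raise BasisError(f"autoaux level must be 'tz' or 'qz', got {level!r}")
    orb = shells_for(orbital_basis, element)
    all_exps = np.concatenate([s.exps for s in orb])
    lmax = max(s.l for s in orb)
    lo, hi = 2 * all_exps.min() * 0.25, 2 * all_exps.max() * 4.0
    n_tz = max(4, int(math.ceil(math.log(hi / lo) / math.log(2.5))) + 1)
    chain = _even_tempered(lo, hi, n_tz)
    if level == "qz":
        mids = np.sqrt(chain[:-1] * chain[1:])
        chain = np.sort(np.concatenate([chain, mids]))
    lmax_aux = 2 * lmax + 1 + (1 if level == "qz" else 0)
    shells = []
    for l in range(lmax_aux + 1):
        # trim the diffuse tail for higher angular momenta
        keep = chain[chain >= lo * (1.5 ** l)] if l > 0 else chain
        if keep.size == 0:
            keep = chain[-2:]
        for a in keep:
            shells.append(Shell(l, [a], [1.0]))
    return shells


def shells_for(basis_name: str, element: str) -> list[Shell]:
    """Resolve a named basis to contracted shells for one element."""
    name = basis_name.lower()
    m = _ET_PATTERN.match(name)
    if m:
        return even_tempered_nuclear_shells(m.group(1))
    if name.startswith("autoaux-"):
        raise BasisError("autoaux sets need the orbital basis; use autoaux_shells()")
    lib = _library()
    if name not in lib:
        raise BasisError(f"unknown basis set {basis_name!r}; known: {sorted(lib)}")
    entry = lib[name]
    if entry.get("counting_only"):
        raise BasisError(
            f"basis {basis_name!r} ships as a counting-only composition "
            "(no primitives); it cannot be used for integral evaluation")
    elements = entry["elements"]
    if element not in elements:
        raise BasisError(f"basis {basis_name!r} has no entry for element {element!r}")
    return _uncontract(elements[element])


def nfunc_for(basis_name: str, element: str) -> int:
    """Spherical function count of a named basis on one element."""
    name = basis_name.lower()
    m = _ET_PATTERN.match(name)
    if m:
        return composition_nfunc(m.group(1))
    lib = _library()
    if name not in lib:
        raise BasisError(f"unknown basis set {basis_name!r}; known: {sorted(lib)}")
    entry = lib[name]
    if entry.get("counting_only"):
        comp = entry["composition"]
        if element not in comp:
            raise BasisError(f"basis {basis_name!r} has no entry for {element!r}")
        return composition_nfunc(comp[element])
    return sum(s.nfunc for s in _uncontract(entry["elements"][element]))
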