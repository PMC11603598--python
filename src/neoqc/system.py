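"""Molecular/multicomponent model: geometry, quantum-proton selection, counting.

A ``SystemModel`` is the single source of particle and orbital counts:
``n_electrons`` (must be even, closed shell), ``n_quantum_protons`` and the
basis-set assignments for the electronic, nuclear and auxiliary spaces.
Electronic basis functions sit on *all* centres, including quantum protons;
nuclear basis and nuclear fitting functions sit only on quantum-flagged
centres.  Coordinates are accepted in Angstrom and stored in bohr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .basis import BasisError, nfunc_for
from .constants import ATOMIC_NUMBERS, BOHR_PER_ANGSTROM


class ValidationError(ValueError):
    pass


class XYZParseError(ValueError):
    pass


@dataclass(frozen=True)
class AtomSpec:
    """One atom: element symbol, position (bohr), quantum-nucleus flag."""

    element: str
    position: tuple[float, float, float]
    quantum: bool = False

    def __post_init__(self):
        if self.element not in ATOMIC_NUMBERS:
            raise ValidationError(f"unknown element symbol {self.element!r}")
        if self.quantum and self.element != "H":
            raise ValidationError(
                f"only hydrogen may be treated quantum-mechanically, got {self.element}")
        if not all(math.isfinite(x) for x in self.position):
            raise ValidationError("non-finite coordinate")

    @property
    def Z(self) -> int:
        return ATOMIC_NUMBERS[self.element]


@dataclass(frozen=True)
class SystemModel:
    atoms: tuple[AtomSpec, ...]
    charge: int = 0
    basis_electronic: str = "cc-pvtz"
    basis_nuclear: str = "pb4-f2"
    aux_electronic: str = "cc-pvtz-mp2fit"
    aux_nuclear: str = "et-10s10p10d10f"
    provenance: str = ""

    def __post_init__(self):
        if len(self.atoms) == 0:
            raise ValidationError("empty atom list")
        if self.n_electrons < 2:
            raise ValidationError("need at least two electrons")

    @property
    def n_electrons(self) -> int:
        return sum(a.Z for a in self.atoms) - self.charge

    @property
    def n_quantum_protons(self) -> int:
        return sum(a.quantum for a in self.atoms)

    @property
    def quantum_atoms(self) -> tuple[AtomSpec, ...]:
        return tuple(a for a in self.atoms if a.quantum)

    @property
    def classical_atoms(self) -> tuple[AtomSpec, ...]:
        return tuple(a for a in self.atoms if not a.quantum)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def with_basis(self, **kw) -> "SystemModel":
        mapping = {"electronic": "basis_electronic", "nuclear": "basis_nuclear",
                   "aux_electronic": "aux_electronic", "aux_nuclear": "aux_nuclear"}
        return replace(self, **{mapping.get(k, k): v for k, v in kw.items()})


def parse_xyz(text: str, charge: int = 0,
              quantum_selection="all-H") -> SystemModel:
    """Parse a standard two-header-line XYZ string.

    ``quantum_selection`` is either the string ``"all-H"`` or a list of
    1-based atom indices, each of which must refer to a hydrogen.
    """
    lines = text.strip().splitlines()
    if len(lines) < 2:
        raise XYZParseError("XYZ input needs a count line and a comment line")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError("line 1: expected atom count")
    body = lines[2:2 + natoms]
    if len(body) < natoms:
        raise XYZParseError(f"expected {natoms} atom lines, found {len(body)}")
    atoms = []
    for k, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"line {k + 3}: expected 'El x y z'")
        el = parts[0].capitalize()
        try:
            xyz = tuple(float(p) * BOHR_PER_ANGSTROM for p in parts[1:4])
        except ValueError:
            raise XYZParseError(f"line {k + 3}: malformed coordinate")
        atoms.append((el, xyz))
    if quantum_selection == "all-H":
        flags = [el == "H" for el, _ in atoms]
    else:
        flags = [False] * len(atoms)
        for idx in quantum_selection:
            if not (1 <= idx <= len(atoms)):
                raise ValidationError(f"quantum index {idx} out of range (1-based)")
            if atoms[idx - 1][0] != "H":
                raise ValidationError(
                    f"atom {idx} ({atoms[idx - 1][0]}) is not hydrogen; "
                    "only protons may be quantum")
            flags[idx - 1] = True
    specs = tuple(AtomSpec(el, xyz, q) for (el, xyz), q in zip(atoms, flags))
    return SystemModel(atoms=specs, charge=charge)


# ---------------------------------------------------------------- counting

_WHICH = ("electronic", "nuclear", "electronic-aux", "nuclear-aux", "unified-aux")


def count_functions(model: SystemModel, which: str) -> int:
    """Spherical basis-function count for one of the basis spaces.

    Electronic sets count every atom; nuclear sets count quantum protons only;
    the unified auxiliary set is the concatenation of the electronic and
    nuclear fitting sets.
    """
    if which == "electronic":
        return sum(nfunc_for(model.basis_electronic, a.element) for a in model.atoms)
    if which == "nuclear":
        return sum(nfunc_for(model.basis_nuclear, "H") for _ in model.quantum_atoms)
    if which == "electronic-aux":
        return sum(nfunc_for(model.aux_electronic, a.element) for a in model.atoms)
    if which == "nuclear-aux":
        return sum(nfunc_for(model.aux_nuclear, "H") for _ in model.quantum_atoms)
    if which == "unified-aux":
        return count_functions(model, "electronic-aux") + count_functions(model, "nuclear-aux")
    raise ValueError(f"unknown space {which!r}; choose from {_WHICH}")


def count_occupied(model: SystemModel) -> tuple[int, int]:
    """(doubly occupied electronic orbitals, singly occupied nuclear orbitals)."""
    ne = model.n_electrons
    if ne % 2:
        raise ValidationError(f"odd electron count {ne}: open shells unsupported")
    return ne // 2, model.n_quantum_protons


# ---------------------------------------------------------------- fixtures

def _water(origin, donor_dir, up_dir, r_oh=0.9572, ang=104.52):
    """One water: O at origin, first H along donor_dir, second H in the
    donor/up plane at the bend angle.  Lengths in Angstrom."""
    d = np.asarray(donor_dir, float)
    d /= np.linalg.norm(d)
    u = np.asarray(up_dir, float)
    u = u - d * (u @ d)
    u /= np.linalg.norm(u)
    th = math.radians(ang)
    o = np.asarray(origin, float)
    h1 = o + r_oh * d
    h2 = o + r_oh * (math.cos(th) * d + math.sin(th) * u)
    return [("O", o), ("H", h1), ("H", h2)]


def _to_model(entries, charge, quantum="all-H", provenance=""):
    lines = [str(len(entries)), provenance]
    for el, xyz in entries:
        lines.append(f"{el} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
    model = parse_xyz("\n".join(lines), charge=charge, quantum_selection=quantum)
    return replace(model, provenance=provenance)


def _zundel_entries():
    # idealized Zundel cation: O-O 2.40 A, shared proton at the midpoint,
    # two dangling hydrogens per oxygen
    entries = [("H", np.zeros(3))]
    for sgn in (+1.0, -1.0):
        o = np.array([1.20 * sgn, 0.0, 0.0])
        for up in (np.array([0.0, 1.0, 0.35]), np.array([0.0, -1.0, 0.35])):
            d = sgn * np.array([0.55, 0.0, 0.0]) + up
            d /= np.linalg.norm(d)
            entries.append(("H", o + 0.97 * d))
        entries.insert(1 if sgn > 0 else 2, ("O", o))
    # keep element grouping: O O then H's
    os_ = [e for e in entries if e[0] == "O"]
    hs = [e for e in entries if e[0] == "H"]
    return os_ + hs


def _eigen_entries(extra_waters=0):
    """H9O4+ Eigen cation (hydronium core, three accepting waters); up to two
    further waters may be chained onto outer oxygens to give H11O5+/H13O6+."""
    entries = []
    core = np.zeros(3)
    dirs = []
    for k in range(3):
        phi = 2 * math.pi * k / 3
        dirs.append(np.array([math.cos(phi), math.sin(phi), -0.25]))
    dirs = [d / np.linalg.norm(d) for d in dirs]
    entries.append(("O", core))
    hyds = [core + 1.0 * d for d in dirs]
    outer_os = [core + 2.55 * d for d in dirs]
    entries += [("H", h) for h in hyds]
    up = np.array([0.0, 0.0, 1.0])
    tails = []
    for k, (o, d) in enumerate(zip(outer_os, dirs)):
        perp = up - d * (up @ d)
        perp /= np.linalg.norm(perp)
        h1 = o + 0.9572 * (0.55 * perp + 0.835 * d) / np.linalg.norm(0.55 * perp + 0.835 * d)
        h2 = o + 0.9572 * (-0.55 * perp + 0.835 * d) / np.linalg.norm(-0.55 * perp + 0.835 * d)
        entries.append(("O", o))
        entries += [("H", h1), ("H", h2)]
        tails.append((o, (h1 - o) / np.linalg.norm(h1 - o)))
    for j in range(extra_waters):
        o0, d0 = tails[j]
        o_new = o0 + 2.75 * d0
        entries += _water(o_new, d0, np.array([0.3, 0.7, 0.65]) + 0.1 * j)
    return entries


def _water_chain(n):
    entries = []
    for k in range(n):
        entries += _water(np.array([2.8 * k, 0.0, 0.0]),
                          np.array([1.0, 0.0, 0.0]),
                          np.array([0.0, 1.0, 0.0]))
    return entries


FIXTURE_NAMES = (
    "zundel", "eigen", "h11o5", "h13o6", "eigen-tetramer-family",
    "water", "water-chain(n)", "hf-diatomic", "h2-oneproton", "h2-twoproton",
)


def generate_fixture(name: str):
    """Deterministic idealized geometries for tests and benchmarks.

    These stand in for deposited benchmark structures: internal coordinates
    are textbook values (O-H 0.9572 A, HOH 104.52 deg, hydrogen-bond O-O
    2.4-2.8 A), not optimized geometries.  ``eigen-tetramer-family`` returns a
    dict of four synthetic H9O4+ arrangements sharing one composition.
    """
    key = name.strip().lower()
    m = None
    if key.startswith("water-chain(") and key.endswith(")"):
        m = int(key[len("water-chain("):-1])
        if m < 1:
            raise ValidationError("water-chain(n) needs n >= 1")
        return _to_model(_water_chain(m), 0, provenance=f"idealized linear water chain n={m}")
    if key == "water":
        return _to_model(_water_chain(1), 0, provenance="idealized water monomer")
    if key == "zundel":
        return _to_model(_zundel_entries(), 1, provenance="idealized Zundel H5O2+ (O-O 2.40 A)")
    if key == "eigen":
        return _to_model(_eigen_entries(0), 1, provenance="idealized Eigen H9O4+")
    if key == "h11o5":
        return _to_model(_eigen_entries(1), 1, provenance="idealized H11O5+ (Eigen + 1 water)")
    if key == "h13o6":
        return _to_model(_eigen_entries(2), 1, provenance="idealized H13O6+ (Eigen + 2 waters)")
    if key == "eigen-tetramer-family":
        base = _eigen_entries(0)
        out = {}
        for tag, twist in (("ring", 0.0), ("eigen", 0.4), ("cis-zundel", 0.8), ("trans-zundel", 1.2)):
            ents = [(el, np.asarray(x) + (0.05 * twist) * np.array([0, 0, 1]) * (el == "H"))
                    for el, x in base]
            out[tag] = _to_model(ents, 1, provenance=f"synthetic H9O4+ family member {tag}")
        return out
    if key == "hf-diatomic":
        return _to_model([("F", np.zeros(3)), ("H", np.array([0.9168, 0.0, 0.0]))], 0,
                         provenance="idealized HF diatomic (r = 0.9168 A)")
    if key == "h2-oneproton":
        m = _to_model([("H", np.zeros(3)), ("H", np.array([0.7414, 0.0, 0.0]))], 0,
                      quantum=[2], provenance="H2 with one quantum proton (r = 0.7414 A)")
        return m
    if key == "h2-twoproton":
        return _to_model([("H", np.zeros(3)), ("H", np.array([0.7414, 0.0, 0.0]))], 0,
                         quantum=[1, 2], provenance="H2, both protons quantum")
    raise ValidationError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
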