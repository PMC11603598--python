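"""Composite multicomponent energies: NEO(MP2)-X assembly and the
zero-point-energy double-counting helper.

Because the second-order amplitudes of the three interaction channels are
decoupled, the electron-electron correlation can be swapped for a
higher-level electronic energy (label X, e.g. a coupled-cluster value
computed externally) while electron-proton and proton-proton correlation
stay at the NEO-MP2 level:

    E[NEO(MP2)-X] = E_ref(NEO-HF) + E_ee(X) + E_ep(MP2) + E_pp(MP2).

External ee energies are ingested from a one-line key-value file carrying the
method label and a geometry hash that must match the reference; this package
never drives external correlation programs itself.

When comparing composite NEO energies against harmonically zero-point
corrected electronic energies, the stretching mode of a quantum-mechanically
treated hydrogen must be excised from the harmonic ZPE — that motion is
already contained in the multicomponent energy.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .constants import CM1_PER_HARTREE


class CompositeError(ValueError):
    pass


def geometry_hash(model) -> str:
    parts = [f"{a.element}:{a.position[0]:.10f},{a.position[1]:.10f},"
             f"{a.position[2]:.10f}:{int(a.quantum)}" for a in model.atoms]
    parts.append(f"charge={model.charge}")
    return hashlib.sha256(";".join(parts).encode()).hexdigest()[:16]


@dataclass
class CompositeSpec:
    reference_energy: float             # NEO-HF, hartree
    ee_energy: float                    # electron-electron correlation
    ee_source: str                      # "internal-mp2" | "internal-pno-lmp2" | label X
    ep_energy: float
    pp_energy: float
    geometry_hash: str = ""
    ee_geometry_hash: str = ""          # must match for external sources

    def __post_init__(self):
        external = self.ee_source not in ("internal-mp2", "internal-pno-lmp2")
        if external and not self.ee_source:
            raise CompositeError("external ee energy needs a method label")
        if external and self.geometry_hash and \
                self.ee_geometry_hash != self.geometry_hash:
            raise CompositeError(
                f"geometry hash mismatch: reference {self.geometry_hash!r} vs "
                f"ee component {self.ee_geometry_hash!r}")

    @property
    def label(self) -> str:
        if self.ee_source == "internal-mp2":
            return "NEO-MP2"
        if self.ee_source == "internal-pno-lmp2":
            return "NEO-PNO-LMP2"
        return f"NEO(MP2)-{self.ee_source}"


def combine(spec: CompositeSpec) -> tuple[float, dict]:
    """Total composite energy plus a provenance record."""
    for name in ("reference_energy", "ee_energy", "ep_energy", "pp_energy"):
        v = getattr(spec, name)
        if v is None or not np.isfinite(v):
            raise CompositeError(f"missing or non-finite component {name}")
    total = spec.reference_energy + spec.ee_energy + spec.ep_energy + spec.pp_energy
    provenance = {
        "label": spec.label,
        "reference_energy": spec.reference_energy,
        "ee_energy": spec.ee_energy,
        "ee_source": spec.ee_source,
        "ep_energy": spec.ep_energy,
        "pp_energy": spec.pp_energy,
        "geometry_hash": spec.geometry_hash,
        "total": total,
    }
    return total, provenance


def read_ee_file(path) -> tuple[str, float, str]:
    """One-line key-value file: ``method=<X> energy=<hartree> hash=<hex>``."""
    with open(path) as fh:
        text = fh.read().strip()
    kv = dict(tok.split("=", 1) for tok in text.split())
    try:
        return kv["method"], float(kv["energy"]), kv.get("hash", "")
    except KeyError as exc:
        raise CompositeError(f"ee file {path} is missing key {exc}")


def zpe_partition(frequencies_cm1, removed_modes=()) -> float:
    """Harmonic ZPE (hartree) with selected modes excised.

    ``frequencies_cm1`` must be non-negative real harmonic frequencies;
    ``removed_modes`` are 0-based indices of modes (e.g. the X-H stretch of a
    quantum proton) excluded to avoid double counting.
    """
    freqs = np.asarray(frequencies_cm1, dtype=float)
    if np.any(freqs < 0):
        raise CompositeError("imaginary/negative frequencies are not allowed")
    removed = set(int(k) for k in removed_modes)
    for k in removed:
        if not (0 <= k < freqs.size):
            raise CompositeError(f"removed mode index {k} out of range")
    keep = [k for k in range(freqs.size) if k not in removed]
    return float(0.5 * freqs[keep].sum() / CM1_PER_HARTREE)
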