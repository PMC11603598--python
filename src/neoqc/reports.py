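"""Run configuration, pipeline driver and result reports.

The config is a flat typed key-value mapping (also parsable from a simple
``key = value`` text file).  ``run`` executes setup -> integrals -> SCF ->
correlation and returns a report dict with energies per channel, the basis
counts, and the convergence record; ``compare_runs`` tabulates per-channel
deviations between two reports of the same system.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .composite import geometry_hash
from .constants import KCAL_PER_HARTREE
from .correlation import df_neo_mp2, neo_mp2, neo_pno_lmp2
from .local_mp2 import PairThresholds
from .scf import ConvergenceSettings, run_neo_scf
from .system import (SystemModel, count_functions, count_occupied,
                     generate_fixture, parse_xyz)

METHODS = ("neo-hf", "neo-mp2", "df-neo-mp2", "neo-pno-lmp2")


class ConfigError(ValueError):
    pass


_KNOWN_KEYS = {
    "geometry", "fixture", "charge", "quantum_nuclei", "method",
    "basis.electronic", "basis.nuclear", "aux.electronic", "aux.nuclear",
    "ep_screen_radius", "local.close", "local.weak", "local.distant",
    "local.very_distant", "local.pno_occupation", "local.pno_energy_fraction",
    "local.localizer", "scf.overall_energy", "seed", "output",
}


@dataclass
class RunConfig:
    method: str = "neo-hf"
    geometry: str | None = None          # path to an XYZ file
    fixture: str | None = None           # or a named fixture
    charge: int = 0
    quantum_nuclei: object = "all-H"     # "all-H" or 1-based index list
    basis_electronic: str = "sto-3g"
    basis_nuclear: str = "pb4-f2"
    aux_electronic: str = "autoaux-tz"
    aux_nuclear: str = "et-10s10p10d10f"
    ep_screen_radius: float = float("inf")
    thresholds: PairThresholds = field(default_factory=PairThresholds)
    localizer: str = "pipek-mezey"
    scf: ConvergenceSettings = field(default_factory=ConvergenceSettings)
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.geometry is None and self.fixture is None:
            raise ConfigError("config needs either 'geometry' or 'fixture'")


def parse_config_text(text: str) -> RunConfig:
    """Parse flat ``key = value`` lines; unknown keys are rejected."""
    kv = {}
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {ln}: expected 'key = value'")
        k, v = (p.strip() for p in line.split("=", 1))
        if k not in _KNOWN_KEYS:
            raise ConfigError(f"line {ln}: unknown config key {k!r}")
        kv[k] = v
    thr = PairThresholds(
        close=float(kv.pop("local.close", 1e-4)),
        weak=float(kv.pop("local.weak", 1e-5)),
        distant=float(kv.pop("local.distant", 1e-6)),
        very_distant=float(kv.pop("local.very_distant", 1e-7)),
        pno_occupation=float(kv.pop("local.pno_occupation", 1e-8)),
        pno_energy_fraction=float(kv.pop("local.pno_energy_fraction", 0.997)))
    scf = ConvergenceSettings(
        overall_energy=float(kv.pop("scf.overall_energy", 1e-7)))
    quantum = kv.pop("quantum_nuclei", "all-H")
    if quantum != "all-H":
        quantum = [int(t) for t in quantum.replace(",", " ").split()]
    kv.pop("output", None)
    return RunConfig(
        method=kv.pop("method", "neo-hf"),
        geometry=kv.pop("geometry", None),
        fixture=kv.pop("fixture", None),
        charge=int(kv.pop("charge", 0)),
        quantum_nuclei=quantum,
        basis_electronic=kv.pop("basis.electronic", "sto-3g"),
        basis_nuclear=kv.pop("basis.nuclear", "pb4-f2"),
        aux_electronic=kv.pop("aux.electronic", "autoaux-tz"),
        aux_nuclear=kv.pop("aux.nuclear", "et-10s10p10d10f"),
        ep_screen_radius=float(kv.pop("ep_screen_radius", "inf")),
        localizer=kv.pop("local.localizer", "pipek-mezey"),
        thresholds=thr, scf=scf, seed=int(kv.pop("seed", 0)))


def _build_model(config: RunConfig) -> SystemModel:
    if config.fixture is not None:
        model = generate_fixture(config.fixture)
        if config.quantum_nuclei != "all-H":
            from dataclasses import replace
            from .system import AtomSpec
            flags = set(config.quantum_nuclei)
            model = replace(model, atoms=tuple(
                AtomSpec(a.element, a.position, (k + 1) in flags)
                for k, a in enumerate(model.atoms)))
    else:
        with open(config.geometry) as fh:
            model = parse_xyz(fh.read(), charge=config.charge,
                              quantum_selection=config.quantum_nuclei)
    return model.with_basis(electronic=config.basis_electronic,
                            nuclear=config.basis_nuclear,
                            aux_electronic=config.aux_electronic,
                            aux_nuclear=config.aux_nuclear)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps({k: repr(v) for k, v in vars(config).items()},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute the pipeline for one configuration and return the report."""
    model = _build_model(config)
    report = {
        "version": __version__,
        "method": config.method,
        "config_hash": _config_hash(config),
        "geometry_hash": geometry_hash(model),
        "charge": model.charge,
        "n_electrons": model.n_electrons,
        "n_quantum_protons": model.n_quantum_protons,
        "occupied_electronic": count_occupied(model)[0],
        "occupied_nuclear": count_occupied(model)[1],
        "basis_functions_electronic": count_functions(model, "electronic"),
        "basis_functions_nuclear": count_functions(model, "nuclear"),
    }
    try:
        state = run_neo_scf(model, config.scf)
    except Exception as exc:
        raise RuntimeError(f"stage scf: {exc}") from exc
    report["E_neo_hf"] = state.energy
    report["scf_iterations"] = len(state.history)
    if config.method == "neo-hf":
        return report
    try:
        if config.method == "neo-mp2":
            res = neo_mp2(state)
        elif config.method == "df-neo-mp2":
            res = df_neo_mp2(state, config.aux_electronic, config.aux_nuclear,
                             ep_screen_radius=config.ep_screen_radius)
        else:
            res, records, domains, info = neo_pno_lmp2(
                state, config.aux_electronic, config.aux_nuclear,
                thresholds=config.thresholds, localizer=config.localizer,
                ep_screen_radius=config.ep_screen_radius)
            report["pair_records"] = [
                {"i": r.i, "j": r.j, "class": r.cls, "n_pno": r.n_pno,
                 "estimate": r.estimate, "energy": r.energy} for r in records]
    except Exception as exc:
        raise RuntimeError(f"stage correlation: {exc}") from exc
    report.update({
        "E_ee": res.E_ee, "E_ep": res.E_ep, "E_pp": res.E_pp,
        "E_corr_total": res.total,
        "E_total": state.energy + res.total,
    })
    report["correlation_metadata"] = {
        k: v for k, v in res.metadata.items() if isinstance(v, (int, float, str))}
    return report


def compare_runs(report_a: dict, report_b: dict) -> dict:
    """Per-channel absolute deviations in hartree and kcal/mol."""
    if report_a.get("geometry_hash") != report_b.get("geometry_hash"):
        raise ConfigError("cannot compare runs on different systems "
                          "(geometry hash mismatch)")
    table = {}
    for key in ("E_neo_hf", "E_ee", "E_ep", "E_pp", "E_corr_total", "E_total"):
        if key in report_a and key in report_b:
            d = abs(report_a[key] - report_b[key])
            table[key] = {"hartree": d, "kcal_per_mol": d * KCAL_PER_HARTREE}
    return table


def format_report(report: dict) -> str:
    """Human-readable key-value report (hartree to 10 decimals)."""
    lines = []
    for k, v in report.items():
        if isinstance(v, float):
            lines.append(f"{k:32s} = {v:.10f}")
        elif isinstance(v, (str, int)):
            lines.append(f"{k:32s} = {v}")
    return "\n".join(lines)
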