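"""Run configuration: one YAML file with explicit units in the key names.

All lengths are given in um, times in s, pressures in Pa and moduli in GPa at
the surface; conversion to a single SI system (m, s, Pa) happens once inside
the solvers, avoiding the mixed-unit hazards of N/mm^2 vs Pa vs g/cm^3.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .geometry import GeometrySpec
from .materials import GROUP_BVTV, MaterialSpec, material_for_group
from .waveforms import LoadSpec

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class SolverConfig:
    rtol: float = 1e-8
    n_steps: int = 20
    method: str = "fast"


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation batch."""

    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    material: MaterialSpec = field(default_factory=MaterialSpec)
    load: LoadSpec = field(default_factory=LoadSpec)
    solver: SolverConfig = field(default_factory=SolverConfig)
    out_dir: str = "results"
    seeds: tuple = (0,)

    def to_dict(self) -> dict:
        return {
            "geometry": {
                "grid_n": self.geometry.grid_n,
                "margin_vox": self.geometry.margin_vox,
                "bvtv_target": self.geometry.bvtv_target,
                "correlation_length_um": self.geometry.correlation_length,
                "pitch_um": self.geometry.pitch,
                "seed": self.geometry.seed,
            },
            "material": asdict(self.material),
            "load": {
                "B_um": self.load.B,
                "T_s": self.load.T,
                "C_pa": self.load.C,
                "k_value": self.load.k_value,
                "k_units": self.load.k_units,
                "U0_um": self.load.U0,
            },
            "solver": asdict(self.solver),
            "out_dir": self.out_dir,
            "seeds": list(self.seeds),
        }


def _geometry_from(d: dict) -> GeometrySpec:
    return GeometrySpec(
        grid_n=int(d.get("grid_n", 48)),
        margin_vox=int(d.get("margin_vox", 2)),
        bvtv_target=float(d.get("bvtv_target", 0.30)),
        correlation_length=float(d.get("correlation_length_um", 120.0)),
        pitch=float(d.get("pitch_um", 18.0)),
        seed=int(d.get("seed", 0)),
    )


def _material_from(d: dict) -> MaterialSpec:
    if "group" in d and "E_gpa" not in d:
        mat = material_for_group(d["group"])
    else:
        mat = MaterialSpec(
            E=float(d.get("E_gpa", 15.08)),
            nu=float(d.get("nu", 0.3)),
            rho_fluid=float(d.get("rho_g_cm3", 0.95)),
            mu_fluid=float(d.get("mu_pa_s", 85.5)),
            group_label=str(d.get("group", "custom")),
        )
    return mat


def _load_from(d: dict) -> LoadSpec:
    return LoadSpec(
        B=float(d.get("B_um", 0.8)),
        T=float(d.get("T_s", 1.0)),
        C=float(d.get("C_pa", 667.0)),
        k_value=float(d.get("k_value", 16e9)),
        k_units=str(d.get("k_units", "N/mm^2/mm")),
        U0=float(d.get("U0_um", 0.0)),
    )


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration; missing keys take study defaults.

    A material section with only a group name pulls that group's modulus,
    and a geometry section without bvtv_target inherits the group's BV/TV.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    try:
        geom_d = dict(raw.get("geometry", {}))
        mat = _material_from(dict(raw.get("material", {})))
        if "bvtv_target" not in geom_d and mat.group_label in GROUP_BVTV:
            geom_d["bvtv_target"] = GROUP_BVTV[mat.group_label]
        geom = _geometry_from(geom_d)
        load = _load_from(dict(raw.get("load", {})))
        sol_d = dict(raw.get("solver", {}))
        solver = SolverConfig(
            rtol=float(sol_d.get("rtol", 1e-8)),
            n_steps=int(sol_d.get("n_steps", 20)),
            method=str(sol_d.get("method", "fast")),
        )
        seeds = raw.get("seeds", [geom.seed])
        if isinstance(seeds, int):
            seeds = [seeds]
        return RunConfig(
            geometry=geom, material=mat, load=load, solver=solver,
            out_dir=str(raw.get("out_dir", "results")),
            seeds=tuple(int(s) for s in seeds),
        )
    except (TypeError, ValueError, KeyError) as exc:
        raise ValueError(f"invalid config {path!r}: {exc}") from exc


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the resolved configuration (provenance)."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
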