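"""Structured run configuration: YAML in, validated and unit-normalised.

All lengths are um, forces nN, stiffnesses nN/um.  Elastic moduli accept a
bare number (Pa) or a string with an explicit unit suffix ("2.6 GPa",
"244 MPa"); loads accept nN or a string in pN/nN.  Unknown keys are
rejected.  An empty file yields the documented defaults, which reproduce
the published material table exactly.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import units
from .mechanics import MaterialTable, default_materials
from .origami import DEFAULT_LOAD_NN, DEFAULT_PRESTRAIN, VARIANTS, FoldConfig
from .solver import SolverSettings

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "parse_modulus",
           "parse_force"]


class ConfigError(ValueError):
    """A configuration key failed validation; the message names the key and
    the expected units."""


_MOD_UNITS = {"pa": 1.0, "kpa": 1e3, "mpa": 1e6, "gpa": 1e9}
_FORCE_UNITS = {"nn": 1.0, "pn": units.PN_TO_NN, "un": 1e3}


def _parse_quantity(value, table, kind, key):
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([A-Za-z]+)\s*", str(value))
    if not m:
        raise ConfigError(f"{key}: cannot parse {kind} {value!r}")
    num, unit = float(m.group(1)), m.group(2).lower()
    if unit not in table:
        raise ConfigError(f"{key}: unknown {kind} unit {m.group(2)!r}; "
                          f"expected one of {sorted(table)}")
    return num * table[unit]


def parse_modulus(value, key="modulus") -> float:
    """Modulus in Pa; bare numbers are Pa, strings carry a suffix."""
    return _parse_quantity(value, _MOD_UNITS, "modulus", key)


def parse_force(value, key="load") -> float:
    """Force in nN; bare numbers are nN, strings carry a suffix (pN/nN/uN)."""
    return _parse_quantity(value, _FORCE_UNITS, "force", key)


_FILAMENT_KEYS = ("MT_strut", "MF_cable", "IF_cable", "lamina_strut", "chromatin_cable")


@dataclass
class RunConfig:
    """Full resolved configuration of one simulation run."""

    variant: str = "CSK12"
    # plate geometry, um
    b: float = 30.0
    h: float = 2.7
    w: float = 6.0
    t: float = 0.3
    # cell geometry, um
    footprint_radius: float = 12.0
    cell_height: float = 6.0
    nsk_radius: float | None = None
    # prestrain (dimensionless) and traction load (nN per farthest node)
    eps_cable: float = DEFAULT_PRESTRAIN
    eps_strut: float = DEFAULT_PRESTRAIN
    load: float = DEFAULT_LOAD_NN
    # plate mesh resolution, um
    resolution: float = 3.0
    # focal-adhesion bond stiffness, nN/um
    k_b: float = 0.025
    # materials: kind -> {modulus (Pa or suffixed string), poisson, area_nm2}
    materials: dict = field(default_factory=dict)
    plate_modulus: float = 4e9   # Pa
    plate_poisson: float = 0.3
    joint_modulus: float = 4e9   # Pa
    joint_poisson: float = 0.3
    # solver
    residual_tol: float = 1e-6
    max_iterations: int = 120
    n_load_steps: int = 10
    output_dir: str = "runs"
    export_vtk: bool = True
    export_csv: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant: {self.variant!r} is not one of {VARIANTS}")
        for key in ("b", "h", "w", "t", "footprint_radius", "cell_height",
                    "resolution", "residual_tol"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key}: must be positive (um)")
        if self.k_b <= 0:
            raise ConfigError("k_b: bond stiffness must be positive (nN/um)")
        if not 0 <= self.eps_cable < 1:
            raise ConfigError("eps_cable: cable prestrain must lie in [0, 1)")
        if self.eps_strut < 0:
            raise ConfigError("eps_strut: strut prestrain must be non-negative")
        if self.load < 0:
            raise ConfigError("load: traction magnitude must be non-negative (nN)")
        for kind in self.materials:
            if kind not in _FILAMENT_KEYS:
                raise ConfigError(f"materials.{kind}: unknown element kind; "
                                  f"expected one of {_FILAMENT_KEYS}")

    # -- conversion to runtime objects --------------------------------------

    def material_table(self) -> MaterialTable:
        table = default_materials()
        table.k_b = self.k_b
        for kind, entry in self.materials.items():
            base = table.filaments[kind]
            E = parse_modulus(entry.get("modulus", base[0]), f"materials.{kind}.modulus")
            nu = float(entry.get("poisson", base[1]))
            A = float(entry.get("area_nm2", base[2]))
            if E <= 0 or A <= 0:
                raise ConfigError(f"materials.{kind}: modulus and area must be positive")
            table.filaments[kind] = (E, nu, A)
        table.solids["plate"] = (parse_modulus(self.plate_modulus, "plate_modulus"),
                                 self.plate_poisson)
        table.solids["joint"] = (parse_modulus(self.joint_modulus, "joint_modulus"),
                                 self.joint_poisson)
        return table

    def fold_config(self) -> FoldConfig:
        return FoldConfig(
            variant=self.variant, b=self.b, h=self.h, w=self.w, t=self.t,
            footprint_radius=self.footprint_radius, cell_height=self.cell_height,
            nsk_radius=self.nsk_radius, eps_cable=self.eps_cable,
            eps_strut=self.eps_strut, load=parse_force(self.load, "load"),
            resolution=self.resolution,
            settings=SolverSettings(residual_tol=self.residual_tol,
                                    max_iterations=self.max_iterations,
                                    n_load_steps=self.n_load_steps))

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration; empty file = defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}; "
                          f"known keys: {sorted(known)}")
    if "load" in raw:
        raw["load"] = parse_force(raw["load"], "load")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
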