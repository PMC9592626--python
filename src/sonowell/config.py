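"""YAML/JSON configuration for the well model.

Schema (all sections optional; omitted values fall back to the reference
water-well defaults).  Keys carry the practical units of the ultrasound
literature and are converted to SI on load::

    medium:
      density_kg_m3: 998.0
      dynamic_viscosity_mpa_s: 0.890
      bulk_viscosity_mpa_s: 2.485
      sound_speed_m_s: 1497.0
    geometry:
      basis_radius_mm: 7.950
      solution_height_mm: 10.78
      base_thickness_mm: 1.3
    impedances:
      lateral_pa_s_m: 2.5e6
      top_pa_s_m: 4.017e2
    drive:
      frequency_mhz: 1.0
      input_power_w_cm2: 0.45
      attenuation_per_cm: 0.108
    solver:
      refinement: 1.0
      lateral_condition: impedance
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import yaml

from .parameters import (
    BoundaryImpedances,
    MediumProperties,
    SourceDrive,
    WellGeometry,
)
from .solver import SolverConfig

__all__ = ["WellModelConfig", "load_config"]


@dataclass(frozen=True)
class WellModelConfig:
    """Fully resolved model configuration in SI units."""

    medium: MediumProperties
    geometry: WellGeometry
    impedances: BoundaryImpedances
    drive: SourceDrive
    solver: SolverConfig

    def with_power(self, power_w_cm2: float) -> "WellModelConfig":
        """Same configuration at a different input power density [W/cm^2]."""
        drive = SourceDrive.from_practical(
            power_w_cm2,
            medium=self.medium,
            geometry=self.geometry,
            frequency=self.drive.frequency,
            attenuation_per_cm=self.drive.attenuation_coefficient / 1e2,
        )
        return WellModelConfig(
            medium=self.medium,
            geometry=self.geometry,
            impedances=self.impedances,
            drive=drive,
            solver=self.solver,
        )


def _section(data: dict, name: str) -> dict:
    value = data.get(name, {}) or {}
    if not isinstance(value, dict):
        raise ValueError(f"config section {name!r} must be a mapping")
    return value


def load_config(path: str | None = None) -> WellModelConfig:
    """Load a YAML (or JSON) configuration file; ``None`` yields the defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        data = (json.loads(text) if path.endswith(".json") else yaml.safe_load(text)) or {}

    med = _section(data, "medium")
    medium = MediumProperties(
        density=med.get("density_kg_m3", 998.0),
        dynamic_viscosity=med.get("dynamic_viscosity_mpa_s", 0.890) * 1e-3,
        bulk_viscosity=med.get("bulk_viscosity_mpa_s", 2.485) * 1e-3,
        sound_speed=med.get("sound_speed_m_s", 1497.0),
    )
    geo = _section(data, "geometry")
    geometry = WellGeometry(
        basis_radius=geo.get("basis_radius_mm", 7.950) * 1e-3,
        solution_height=geo.get("solution_height_mm", 10.78) * 1e-3,
        base_thickness=geo.get("base_thickness_mm", 1.3) * 1e-3,
    )
    imp = _section(data, "impedances")
    impedances = BoundaryImpedances(
        lateral_impedance=imp.get("lateral_pa_s_m", 2.5e6),
        top_impedance=imp.get("top_pa_s_m", 4.017e2),
    )
    drv = _section(data, "drive")
    drive = SourceDrive.from_practical(
        drv.get("input_power_w_cm2", 0.45),
        medium=medium,
        geometry=geometry,
        frequency=drv.get("frequency_mhz", 1.0) * 1e6,
        attenuation_per_cm=drv.get("attenuation_per_cm", 0.108),
    )
    sol = _section(data, "solver")
    solver = SolverConfig(
        refinement=sol.get("refinement", 1.0),
        lateral_condition=sol.get("lateral_condition", "impedance"),
    )
    return WellModelConfig(
        medium=medium, geometry=geometry, impedances=impedances, drive=drive, solver=solver
    )
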