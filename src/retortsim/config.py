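"""YAML configuration loading: geometry, properties, schedule, solver.

Example document:

    geometry:
      inner_diameter: 98.9    # mm
      height: 121             # mm
      wall_thickness: 0.2     # mm
      headspace: 5            # mm
    properties: chestnut_puree   # or an inline block, see properties.from_dict
    schedule:
      notation: "10-86-24/121"
      cooling_water_C: 25
    solver:
      mode: convection
      grid: [24, 48]
      dt: 1.0

Geometry lengths are millimetres (converted to metres here); an inline
properties block lists polynomial coefficients lowest-order-first with
required unit annotations.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .geometry import CanGeometry, build_mesh
from .properties import ThermoPhysicalProperties, chestnut_puree, from_dict
from .schedule import RetortSchedule, parse_schedule
from .solver import SolverConfig

__all__ = ["load_config", "geometry_from_dict", "properties_from_config"]

MM = 1e-3


def geometry_from_dict(block: dict) -> CanGeometry:
    """Geometry block with lengths in millimetres."""
    try:
        if "inner_diameter" in block:
            radius = float(block["inner_diameter"]) * MM / 2.0
        else:
            radius = float(block["inner_radius"]) * MM
        return CanGeometry(
            inner_radius=radius,
            inner_height=float(block["height"]) * MM,
            wall_thickness=float(block.get("wall_thickness", 0.2)) * MM,
            headspace_height=float(block.get("headspace", 5.0)) * MM,
        )
    except KeyError as exc:
        raise KeyError(f"geometry config missing {exc}") from None


def properties_from_config(entry) -> ThermoPhysicalProperties:
    if entry is None or entry == "chestnut_puree":
        return chestnut_puree()
    if isinstance(entry, dict):
        return from_dict(entry)
    raise ValueError(f"unknown properties entry {entry!r}")


def load_config(path) -> tuple[SolverConfig, RetortSchedule]:
    """Read a YAML file into a ready-to-run (SolverConfig, RetortSchedule)."""
    doc = yaml.safe_load(Path(path).read_text())
    geometry = geometry_from_dict(doc.get("geometry", {})) \
        if "geometry" in doc else None
    props = properties_from_config(doc.get("properties"))
    solver = doc.get("solver", {})
    nr, nz = solver.get("grid", [24, 48])
    from .geometry import default_can
    mesh = build_mesh(geometry or default_can(), nr=int(nr), nz=int(nz))
    config = SolverConfig(
        mesh=mesh,
        properties=props,
        mode=solver.get("mode", "convection"),
        dt=float(solver.get("dt", 1.0)),
        initial_temperature=float(solver.get("initial_temperature_K", 341.15)),
    )
    sched_block = doc.get("schedule", {})
    schedule = parse_schedule(
        sched_block["notation"],
        come_up_start=config.initial_temperature,
        cooling_water=float(sched_block.get("cooling_water_C", 25.0)) + 273.15,
    )
    return config, schedule
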