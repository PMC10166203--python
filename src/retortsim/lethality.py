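"""F-value (lethality) accumulation, cold-point location and quality metrics.

The sterilizing effect at a point is the time integral of the lethal rate

    L(T) = 10^((T_degC - RT) / Z)

with reference temperature RT = 121.1 degC and Z = 10 degC (Clostridium
botulinum reference); F = int L dt is reported in minutes at RT.  The cell
with the lowest accumulated F is the cold point (slowest heating zone), the
location that limits commercial sterility.  Cells with F above a quality
threshold (25 min by default) form the overheated zone — the browning proxy
used to score schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AxiMesh

__all__ = [
    "LethalityConfig",
    "LethalityField",
    "lethal_rate",
    "accumulate",
    "cold_point",
    "overheated_fraction",
]

C_TO_K = 273.15


@dataclass(frozen=True)
class LethalityConfig:
    reference_temperature: float = 121.1  # degC
    z_value: float = 10.0                 # degC
    overheat_threshold: float = 25.0      # min
    target_F: float = 4.5                 # min, commercial-sterility requirement

    def __post_init__(self):
        if self.z_value <= 0 or self.reference_temperature <= 0 \
                or self.overheat_threshold <= 0:
            raise ValueError("RT, Z and overheat_threshold must be positive")


@dataclass
class LethalityField:
    """Accumulated F(r, z) in minutes on a mesh, with summary statistics."""

    mesh: AxiMesh
    config: LethalityConfig
    F: np.ndarray = None  # (nr, nz) minutes

    def __post_init__(self):
        if self.F is None:
            self.F = np.zeros((self.mesh.nr, self.mesh.nz))

    @property
    def F_min(self) -> float:
        return float(self.F[self.mesh.puree_mask].min())

    @property
    def F_max(self) -> float:
        return float(self.F[self.mesh.puree_mask].max())

    @property
    def cold_point(self) -> tuple[float, float]:
        r, z, _ = cold_point(self, self.mesh)
        return (r, z)

    @property
    def oz_fraction(self) -> float:
        return overheated_fraction(self, self.mesh, self.config.overheat_threshold)


def lethal_rate(T, config: LethalityConfig = LethalityConfig()):
    """Dimensionless lethal rate 10^((T_degC - RT)/Z) for T in kelvin."""
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    rate = 10.0 ** ((T - C_TO_K - config.reference_temperature) / config.z_value)
    return float(rate) if rate.ndim == 0 else rate


def accumulate(
    field: LethalityField,
    T_field: np.ndarray,
    dt: float,
    config: LethalityConfig | None = None,
    T_field_prev: np.ndarray | None = None,
) -> LethalityField:
    """Add one time interval's lethality to ``field`` (in place; returns it).

    With only ``T_field``, a rectangle rule ``F += L(T) dt/60`` is used; when
    the previous step's field is also supplied, the trapezoid of the two
    lethal rates is taken.
    """
    config = config or field.config
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T_field.shape != field.F.shape:
        raise ValueError(
            f"temperature field shape {T_field.shape} does not match mesh "
            f"{field.F.shape}"
        )
    rate = lethal_rate(T_field, config)
    if T_field_prev is not None:
        rate = 0.5 * (rate + lethal_rate(T_field_prev, config))
    field.F += rate * (dt / 60.0)
    return field


def cold_point(field: LethalityField, mesh: AxiMesh) -> tuple[float, float, float]:
    """Cell-center (r, z) and F of the minimum-F puree cell.

    Ties break deterministically toward the smallest z, then the smallest r.
    """
    if not mesh.puree_mask.any():
        raise ValueError("mesh has no puree cells")
    F = np.where(mesh.puree_mask, field.F, np.inf)
    fmin = F.min()
    # candidates within exact tie of the minimum; scan z-major then r
    ii, jj = np.nonzero(F == fmin)
    order = np.lexsort((ii, jj))  # smallest z first, then smallest r
    i, j = ii[order[0]], jj[order[0]]
    return float(mesh.r_centers[i]), float(mesh.z_centers[j]), float(fmin)


def overheated_fraction(
    field: LethalityField, mesh: AxiMesh, threshold: float | None = None
) -> float:
    """Puree-volume fraction with F above ``threshold`` minutes."""
    if threshold is None:
        threshold = field.config.overheat_threshold
    vol = mesh.cell_volumes
    hot = (field.F > threshold) & mesh.puree_mask
    return float(vol[hot].sum() / vol[mesh.puree_mask].sum())
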