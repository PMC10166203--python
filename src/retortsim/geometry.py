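"""Can geometry and the axisymmetric structured mesh.

Coordinates: ``r`` in [0, R] with r = 0 the symmetry axis, ``z`` in [0, H]
with z = 0 the inner surface of the can bottom.  The thin metal wall
(0.2 mm) is not meshed — it is treated as thermally transparent, so the
inner surface sees the retort temperature directly.  The headspace (vapor
gap below the lid) occupies the top rows of cells; its boundary is snapped
to the nearest cell edge and the realized height is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CanGeometry", "AxiMesh", "build_mesh", "default_can"]


@dataclass(frozen=True)
class CanGeometry:
    """Inner dimensions of a cylindrical can, metres."""

    inner_radius: float
    inner_height: float
    wall_thickness: float = 0.0002
    headspace_height: float = 0.005

    def __post_init__(self):
        for name in ("inner_radius", "inner_height", "wall_thickness",
                     "headspace_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.headspace_height >= self.inner_height:
            raise ValueError("headspace_height must be smaller than inner_height")


def default_can() -> CanGeometry:
    """The #9121 tin: inner diameter 98.9 mm, height 121 mm, 5 mm headspace."""
    return CanGeometry(inner_radius=0.0989 / 2, inner_height=0.121,
                       wall_thickness=0.0002, headspace_height=0.005)


@dataclass(frozen=True)
class AxiMesh:
    """Uniform structured axisymmetric grid of cylindrical-shell cells.

    Cell (i, j) spans [r_edges[i], r_edges[i+1]] x [z_edges[j], z_edges[j+1]]
    and has volume 2 pi r_c dr dz.  ``puree_mask[i, j]`` is True for product
    cells; the complementary rows at the top are headspace.
    """

    geometry: CanGeometry
    nr: int
    nz: int
    r_edges: np.ndarray   # (nr+1,)
    z_edges: np.ndarray   # (nz+1,)
    r_centers: np.ndarray  # (nr,)
    z_centers: np.ndarray  # (nz,)
    cell_volumes: np.ndarray  # (nr, nz)
    puree_mask: np.ndarray    # (nr, nz) bool
    realized_headspace: float  # m, after snapping to a cell edge

    @property
    def dr(self) -> float:
        return float(self.r_edges[1] - self.r_edges[0])

    @property
    def dz(self) -> float:
        return float(self.z_edges[1] - self.z_edges[0])

    @property
    def n_puree_rows(self) -> int:
        """Number of axial cell rows below the headspace interface."""
        return int(self.puree_mask[0].sum())

    @property
    def puree_surface_z(self) -> float:
        """Axial position of the puree/headspace interface (a cell edge)."""
        return float(self.z_edges[self.n_puree_rows])

    @property
    def puree_volume(self) -> float:
        return float(self.cell_volumes[self.puree_mask].sum())

    @property
    def total_volume(self) -> float:
        return float(self.cell_volumes.sum())

    def volume_average(self, field: np.ndarray, puree_only: bool = False) -> float:
        """Volume-weighted mean of a cell field."""
        if puree_only:
            w = self.cell_volumes[self.puree_mask]
            return float((field[self.puree_mask] * w).sum() / w.sum())
        return float((field * self.cell_volumes).sum() / self.cell_volumes.sum())


def build_mesh(geometry: CanGeometry, nr: int = 24, nz: int = 48,
               include_headspace: bool = True) -> AxiMesh:
    """Build a uniform axisymmetric grid over the can interior.

    The headspace boundary is snapped to the nearest interior cell edge; the
    realized headspace therefore differs from the nominal one by at most
    half a cell.  Requires nr, nz >= 4 and a headspace resolved by at least
    one cell row after snapping.  ``include_headspace=False`` builds a
    brim-full can (every cell puree) for symmetric conduction checks.
    """
    if nr < 4 or nz < 4:
        raise ValueError(f"mesh too coarse: need nr >= 4 and nz >= 4, got {nr}x{nz}")
    R, H = geometry.inner_radius, geometry.inner_height
    r_edges = np.linspace(0.0, R, nr + 1)
    z_edges = np.linspace(0.0, H, nz + 1)
    r_c = 0.5 * (r_edges[:-1] + r_edges[1:])
    z_c = 0.5 * (z_edges[:-1] + z_edges[1:])
    dr = R / nr
    dz = H / nz

    # volume of the cylindrical shell cell: 2 pi r_c dr dz
    vol = (2.0 * np.pi * r_c * dr * dz)[:, None] * np.ones((1, nz))

    if include_headspace:
        # snap the headspace interface to the nearest cell edge (>= 1 row)
        n_head = int(round(geometry.headspace_height / dz))
        n_head = max(1, min(n_head, nz - 1))
        realized = n_head * dz
        if abs(realized - geometry.headspace_height) > 1e-12:
            logger.info(
                "headspace snapped from %.4g m to %.4g m (%d cell rows)",
                geometry.headspace_height, realized, n_head,
            )
    else:
        n_head, realized = 0, 0.0
    puree = np.ones((nr, nz), dtype=bool)
    puree[:, nz - n_head:] = False

    return AxiMesh(
        geometry=geometry, nr=nr, nz=nz,
        r_edges=r_edges, z_edges=z_edges,
        r_centers=r_c, z_centers=z_c,
        cell_volumes=vol, puree_mask=puree,
        realized_headspace=realized,
    )
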