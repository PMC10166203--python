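"""Field and series export: legacy-VTK structured grids and long-format CSV.

The legacy VTK writer emits ASCII STRUCTURED_GRID files of the (r, z)
half-plane (cell-centre points, one POINT_DATA scalar per field), readable
by ParaView and meshio.  CSV exports are long-format (r, z, value) via
pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import AxiMesh

__all__ = ["write_vtk", "fields_to_csv", "probe_to_csv"]


def write_vtk(path, mesh: AxiMesh, fields: dict, title: str = "retortsim") -> None:
    """Write cell-centre fields as a legacy-VTK ASCII structured grid.

    ``fields`` maps scalar names to (nr, nz) arrays.  Points are the cell
    centres embedded in the x-z plane (y = 0).
    """
    nr, nz = mesh.nr, mesh.nz
    for name, arr in fields.items():
        if arr.shape != (nr, nz):
            raise ValueError(f"field {name!r} has shape {arr.shape}, "
                             f"expected {(nr, nz)}")
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nr} {nz} 1",
        f"POINTS {nr * nz} double",
    ]
    for j in range(nz):
        for i in range(nr):
            lines.append(f"{mesh.r_centers[i]:.9g} 0 {mesh.z_centers[j]:.9g}")
    lines.append(f"POINT_DATA {nr * nz}")
    for name, arr in fields.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK structured order: i fastest, then j
        lines.extend(f"{v:.9g}" for v in arr.T.ravel())
    Path(path).write_text("\n".join(lines) + "\n")


def fields_to_csv(path, mesh: AxiMesh, fields: dict) -> pd.DataFrame:
    """Long-format (r, z, region, field...) CSV of cell-centre fields."""
    rr, zz = np.meshgrid(mesh.r_centers, mesh.z_centers, indexing="ij")
    data = {
        "r_m": rr.ravel(),
        "z_m": zz.ravel(),
        "region": np.where(mesh.puree_mask, "puree", "headspace").ravel(),
    }
    for name, arr in fields.items():
        data[name] = arr.ravel()
    df = pd.DataFrame(data)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def probe_to_csv(path, times, temperatures, lethal_rates=None,
                 fmin_accumulated=None) -> pd.DataFrame:
    """Probe series CSV with the standard columns."""
    data = {"t_s": np.asarray(times), "T_K": np.asarray(temperatures)}
    if lethal_rates is not None:
        data["lethal_rate"] = np.asarray(lethal_rates)
    if fmin_accumulated is not None:
        data["F_min_accumulated"] = np.asarray(fmin_accumulated)
    df = pd.DataFrame(data)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_probe_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a probe CSV; accepts T_K or temperature_K / temperature_C columns."""
    df = pd.read_csv(path)
    tcol = next((c for c in ("t_s", "time_s") if c in df.columns), None)
    if tcol is None:
        raise ValueError("probe CSV needs a t_s or time_s column")
    if "T_K" in df.columns:
        T = df["T_K"].to_numpy(float)
    elif "temperature_K" in df.columns:
        T = df["temperature_K"].to_numpy(float)
    elif "temperature_C" in df.columns:
        T = df["temperature_C"].to_numpy(float) + 273.15
    else:
        raise ValueError("probe CSV needs T_K, temperature_K or temperature_C")
    return df[tcol].to_numpy(float), T
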