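"""Export of meshes, solution fields and Fig.-style plane maps.

Formats: flat CSV of the nodal solution, legacy ASCII VTK structured grid
(readable by ParaView), and per-plane CSV grids plus rasterized PNG maps of
|p|, Re(p) and |I|.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .parameters import WellGeometry
from .postprocess import IntensityField, PlaneSpec
from .solver import PressureField

__all__ = ["export_field_csv", "export_vtk", "export_maps"]

_CSV_FLOAT = "%.10e"


def export_field_csv(field: PressureField, intensity: IntensityField, path: str) -> None:
    """Write the nodal solution as CSV: rho, z, Re p, Im p, |p|, I_rho, I_z, |I|."""
    rr, zz = field.mesh.node_coordinates()
    _, _, ir, iz, imag_ = intensity.nodal()
    df = pd.DataFrame(
        {
            "rho_m": rr,
            "z_m": zz,
            "re_p_Pa": field.p.real,
            "im_p_Pa": field.p.imag,
            "abs_p_Pa": np.abs(field.p),
            "I_rho_W_m2": ir,
            "I_z_W_m2": iz,
            "abs_I_W_m2": imag_,
        }
    )
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)


def export_vtk(field: PressureField, intensity: IntensityField, path: str) -> None:
    """Write the meridian solution as a legacy ASCII VTK structured grid."""
    mesh = field.mesh
    rr, zz = mesh.node_coordinates()
    _, _, ir, iz, imag_ = intensity.nodal()
    n = mesh.n_nodes
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("sonowell axisymmetric pressure field (meridian plane)\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {mesh.nodes_r} {mesh.nodes_z} 1\n")
        fh.write(f"POINTS {n} double\n")
        for x, y in zip(rr, zz):
            fh.write(f"{x:.10e} {y:.10e} 0.0\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, vals in (
            ("re_p", field.p.real),
            ("im_p", field.p.imag),
            ("abs_p", np.abs(field.p)),
            ("abs_I", imag_),
        ):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in vals:
                fh.write(f"{v:.10e}\n")
        fh.write("VECTORS intensity double\n")
        for a, b in zip(ir, iz):
            fh.write(f"{a:.10e} {b:.10e} 0.0\n")


def _plane_grids(plane: PlaneSpec, geometry: WellGeometry, resolution: int):
    """Sampling grid of one plane: (axis1, axis2, rho, z, mask)."""
    r, h = geometry.basis_radius, geometry.solution_height
    if plane.orientation == "vertical":
        half = np.sqrt(max(r**2 - plane.offset**2, 0.0))
        y = np.linspace(-half, half, resolution)
        z = np.linspace(0.0, h, resolution)
        YY, ZZ = np.meshgrid(y, z, indexing="ij")
        return y, z, np.sqrt(plane.offset**2 + YY**2), ZZ, np.ones_like(YY, dtype=bool)
    if plane.orientation == "horizontal":
        x = np.linspace(-r, r, resolution)
        y = np.linspace(-r, r, resolution)
        XX, YY = np.meshgrid(x, y, indexing="ij")
        rho = np.hypot(XX, YY)
        return x, y, np.minimum(rho, r), np.full_like(rho, plane.offset), rho <= r
    raise ValueError("map export is defined for vertical and horizontal planes")


def export_maps(
    field: PressureField,
    intensity: IntensityField,
    planes: list[PlaneSpec],
    outdir: str,
    geometry: WellGeometry | None = None,
    resolution: int = 400,
    pressure_limits: tuple[float, float] | None = None,
    intensity_limits: tuple[float, float] | None = None,
) -> list[str]:
    """Render |p|, Re(p) and |I| on the requested planes as CSV + PNG.

    Returns the list of files written.  PNG raster dimensions equal
    ``resolution x resolution``; color limits default to the per-plane data
    range and can be pinned for cross-power comparability.
    """
    geometry = geometry or WellGeometry(
        basis_radius=field.mesh.radius,
        solution_height=field.mesh.height,
    )
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    for plane in planes:
        plane.validate(geometry)
        a1, a2, rho, z, mask = _plane_grids(plane, geometry, resolution)
        tag = f"{plane.orientation}_{plane.offset * 1e3:.3f}mm"
        p = field.evaluate(rho, z)
        quantities = {
            "abs_p": (np.abs(p), "magma", pressure_limits),
            "re_p": (np.real(p), "RdBu_r", pressure_limits),
            "abs_I": (intensity.magnitude(rho, z), "viridis", intensity_limits),
        }
        for name, (vals, cmap, limits) in quantities.items():
            grid = np.where(mask, vals, np.nan)
            csv_path = os.path.join(outdir, f"{tag}_{name}.csv")
            pd.DataFrame(grid, index=a1, columns=a2).to_csv(csv_path, float_format=_CSV_FLOAT)
            png_path = os.path.join(outdir, f"{tag}_{name}.png")
            vmin, vmax = limits if limits else (np.nanmin(grid), np.nanmax(grid))
            plt.imsave(png_path, grid.T, cmap=cmap, vmin=vmin, vmax=vmax, origin="lower")
            written.extend([csv_path, png_path])
    return written
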