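"""Solution and report writers (VTK legacy ASCII, probe CSV)."""

from __future__ import annotations

import numpy as np

from .mesh import Mesh

__all__ = ["write_vtk", "probe_table"]


def write_vtk(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh and nodal/element fields as legacy VTK ASCII.

    Scalar fields are written as SCALARS, (n,2) fields as 3-component
    VECTORS with zero z, for inspection in ParaView or similar viewers.
    """
    lines = [
        "# vtk DataFile Version 3.0",
        "aaa_ilt slice solution",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.12g} {y:.12g} 0")
    lines.append(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}")
    for tri in mesh.triangles:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["5"] * mesh.n_elements)

    def emit_fields(fields: dict, n: int):
        for name, arr in fields.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.12g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.12g} {v[1]:.12g} 0" for v in arr)

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        emit_fields(point_data, mesh.n_nodes)
    if cell_data:
        lines.append(f"CELL_DATA {mesh.n_elements}")
        emit_fields(cell_data, mesh.n_elements)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def probe_table(labels, values) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    rows = [
        {"kind": kind, "line_angle_deg": ang, "end": end, "displacement_m": float(v)}
        for (kind, ang, end), v in zip(labels, values)
    ]
    return pd.DataFrame(rows)
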