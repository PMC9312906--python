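"""Minimal text-format exporters: legacy-ASCII VTK structured points and CSV.

The legacy VTK format is plain text and readable by ParaView/VisIt; only the
STRUCTURED_POINTS flavor with point-centered scalar fields is needed here.
"""

from __future__ import annotations

import numpy as np


def write_structured_points(path, origin, spacing: float, fields: dict) -> None:
    """Write scalar fields on a uniform grid to a legacy-ASCII VTK file.

    ``fields`` maps names to (nx, ny, nz) arrays sharing one shape; values are
    written in VTK's x-fastest point order.
    """
    fields = {name: np.asarray(a) for name, a in fields.items()}
    shapes = {a.shape for a in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one shape")
    nx, ny, nz = shapes.pop()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("mwablate field snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.6g")


def write_csv(path, header, rows) -> None:
    rows = np.asarray(rows, dtype=float)
    np.savetxt(path, rows, delimiter=",", header=",".join(header), comments="")
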