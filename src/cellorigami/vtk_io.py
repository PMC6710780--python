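"""Minimal legacy-ASCII VTK unstructured-grid writer (lines and hexahedra)."""

from __future__ import annotations

import numpy as np

VTK_LINE = 3
VTK_HEXAHEDRON = 12


def _write_unstructured(path, points, cells, cell_type, point_data=None, cell_data=None):
    points = np.asarray(points, dtype=float)
    cells = [list(map(int, c)) for c in cells]
    n_per = {VTK_LINE: 2, VTK_HEXAHEDRON: 8}[cell_type]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncellorigami\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"CELLS {len(cells)} {len(cells) * (n_per + 1)}\n")
        for c in cells:
            fh.write(" ".join(map(str, [n_per] + c)) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        for _ in cells:
            fh.write(f"{cell_type}\n")
        for header, data in (("POINT_DATA", point_data), ("CELL_DATA", cell_data)):
            if not data:
                continue
            n = len(points) if header == "POINT_DATA" else len(cells)
            fh.write(f"{header} {n}\n")
            for name, values in data.items():
                values = np.asarray(values)
                if values.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in values:
                        fh.write(f"{float(v):.12g}\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for v in values:
                        fh.write(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n")


def write_vtk_lines(path, points, lines, point_data=None, cell_data=None):
    _write_unstructured(path, points, lines, VTK_LINE, point_data, cell_data)


def write_vtk_hexes(path, points, hexes, point_data=None, cell_data=None):
    _write_unstructured(path, points, hexes, VTK_HEXAHEDRON, point_data, cell_data)
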