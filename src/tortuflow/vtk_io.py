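"""Legacy ASCII VTK export of quad meshes and cell fields."""

from __future__ import annotations

import numpy as np

from .meshing import QuadMesh

_PATCH_IDS = {"inlet": 1, "outlet": 2, "wall_lower": 3, "wall_upper": 4}


def write_vtk(mesh: QuadMesh, fname, cell_data: dict | None = None,
              title: str = "tortuflow") -> None:
    """Write the mesh (and optional per-cell scalar fields) as a legacy
    VTK unstructured grid (cell type 9 = quad)."""
    pts = mesh.points
    cells = mesh.cells
    with open(fname, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        for x, y in pts:
            f.write(f"{x:.10g} {y:.10g} 0\n")
        f.write(f"\nCELLS {len(cells)} {len(cells) * 5}\n")
        for c in cells:
            f.write(f"4 {c[0]} {c[1]} {c[2]} {c[3]}\n")
        f.write(f"\nCELL_TYPES {len(cells)}\n")
        f.write("9\n" * len(cells))
        if cell_data:
            f.write(f"\nCELL_DATA {len(cells)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for val in arr:
                    f.write(f"{val:.10g}\n")


def write_boundary_vtk(mesh: QuadMesh, fname) -> None:
    """Write boundary faces as VTK lines tagged with their patch id."""
    faces, tags = [], []
    for name, idx in mesh.patches.items():
        for fi in idx:
            faces.append(mesh.face_nodes[fi])
            tags.append(_PATCH_IDS[name])
    with open(fname, "w") as f:
        f.write("# vtk DataFile Version 3.0\nboundary patches\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(mesh.points)} double\n")
        for x, y in mesh.points:
            f.write(f"{x:.10g} {y:.10g} 0\n")
        f.write(f"\nCELLS {len(faces)} {len(faces) * 3}\n")
        for a, b in faces:
            f.write(f"2 {a} {b}\n")
        f.write(f"\nCELL_TYPES {len(faces)}\n")
        f.write("3\n" * len(faces))
        f.write(f"\nCELL_DATA {len(faces)}\n")
        f.write("SCALARS patch int 1\nLOOKUP_TABLE default\n")
        for t in tags:
            f.write(f"{t}\n")
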