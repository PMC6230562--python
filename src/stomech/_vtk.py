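"""Minimal legacy-ASCII VTK unstructured-grid writer/reader for triangle shell
meshes, including per-cell scalar and vector data. Only the subset of the
legacy format that this package itself produces is supported by the reader."""

from __future__ import annotations

import numpy as np

VTK_TRIANGLE = 5


def write_vtk(path, nodes, triangles, cell_scalars=None, cell_vectors=None,
              point_vectors=None):
    """Write a triangle mesh as a legacy-ASCII VTK unstructured grid.

    cell_scalars / cell_vectors / point_vectors are dicts name -> array.
    """
    nodes = np.asarray(nodes, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    lines = [
        "# vtk DataFile Version 3.0",
        "stomech shell mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in nodes]
    lines.append(f"CELLS {len(triangles)} {4 * len(triangles)}")
    lines += ["3 " + " ".join(str(i) for i in t) for t in triangles]
    lines.append(f"CELL_TYPES {len(triangles)}")
    lines += [str(VTK_TRIANGLE)] * len(triangles)

    if cell_scalars or cell_vectors:
        lines.append(f"CELL_DATA {len(triangles)}")
        for name, arr in (cell_scalars or {}).items():
            arr = np.asarray(arr)
            if arr.dtype.kind in "OUS":
                # encode categorical labels as integer codes with a comment map
                labels, codes = np.unique(arr, return_inverse=True)
                lines.append(f"SCALARS {name} int 1")
                lines.append("LOOKUP_TABLE default")
                lines += [str(int(c)) for c in codes]
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{float(v):.9g}" for v in arr]
        for name, arr in (cell_vectors or {}).items():
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(f"{float(v):.9g}" for v in row) for row in np.asarray(arr)]

    if point_vectors:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, arr in point_vectors.items():
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(f"{float(v):.9g}" for v in row) for row in np.asarray(arr)]

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path):
    """Read back a mesh written by :func:`write_vtk`.

    Returns (nodes, triangles). Cell data is not reconstructed.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)
    nodes = triangles = None
    for line in it:
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            nodes = np.array([[float(v) for v in next(it).split()] for _ in range(n)])
        elif line.startswith("CELLS"):
            m = int(line.split()[1])
            triangles = np.array(
                [[int(v) for v in next(it).split()[1:]] for _ in range(m)], dtype=int
            )
        elif line.startswith("CELL_TYPES"):
            break
    if nodes is None or triangles is None:
        raise ValueError(f"{path}: not a stomech VTK unstructured grid")
    return nodes, triangles
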