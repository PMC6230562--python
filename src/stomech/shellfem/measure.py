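"""Geometry of deformed shell models.

Reads the same measurement set off a simulated (deformed) mesh that the
image morphometry reads off a stack: pore dimensions from the deformed pore
rim projected to the leaf plane, complex dimensions from bounding extents,
arc length along the deformed tube centerline, and guard-cell width from the
mid-cell cross-section diameter.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

from ..meshing import ShellMesh
from ..morphometry import StomatalGeometry


def _polygon_area(pts2d: np.ndarray) -> float:
    x, y = pts2d[:, 0], pts2d[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def measure_model_geometry(result, mesh: ShellMesh) -> StomatalGeometry:
    """Measure the deformed geometry of a simulation result.

    Requires a converged result. Meshes without a pore rim (e.g. spheres
    used for verification) get None pore fields with the bounding extents
    still reported.
    """
    if not result.converged:
        raise ValueError("cannot measure a non-converged result")
    x = mesh.nodes + result.displacements

    geo = {}
    geo["complex_length"] = float(x[:, 0].max() - x[:, 0].min())
    geo["complex_width"] = float(x[:, 1].max() - x[:, 1].min())

    if "pore_rim" in mesh.node_sets:
        rim = x[np.asarray(mesh.node_sets["pore_rim"])][:, :2]
        poly = Polygon(rim)
        if not poly.is_valid:
            raise ValueError("self-intersecting deformed pore boundary")
        geo["pore_length"] = float(rim[:, 0].max() - rim[:, 0].min())
        geo["pore_width"] = float(rim[:, 1].max() - rim[:, 1].min())
        geo["pore_area"] = float(poly.area)
        assert abs(poly.area - _polygon_area(rim)) <= 1e-9 * max(poly.area, 1.0)

    widths, arcs = [], []
    for cell_id, idx in mesh.rings.items():
        idx = np.asarray(idx)
        cent = x[idx].mean(axis=1)
        arcs.append(float(np.linalg.norm(np.diff(cent, axis=0), axis=1).sum()))
        mid = idx.shape[0] // 2
        ring = x[idx[mid]]
        lo, hi = max(mid - 1, 0), min(mid + 1, idx.shape[0] - 1)
        tangent = cent[hi] - cent[lo]
        tangent /= max(np.linalg.norm(tangent), 1e-12)
        m_hat = np.cross(tangent, np.array([0.0, 0.0, 1.0]))
        nm = np.linalg.norm(m_hat)
        if nm > 1e-9:
            m_hat /= nm
            proj = (ring - ring.mean(axis=0)) @ m_hat
            widths.append(float(proj.max() - proj.min()))
    if arcs:
        geo["guard_cell_arc_length"] = float(np.mean(arcs))
    if widths:
        geo["guard_cell_width"] = float(np.mean(widths))
    return StomatalGeometry(**geo)
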