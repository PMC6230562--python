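"""Shell meshes of guard-cell pairs.

Turns landmark rings (traced wall mid-surfaces) or parametric dimensions into
triangulated mid-surface shell meshes carrying per-element thickness, a wall
region label, and a local orthonormal material frame (e1 longitudinal along
the guard-cell tube, e2 circumferential — the cellulose-microfibril hoop
direction — e3 the outward surface normal).

All coordinates are in micrometres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep

from . import _vtk

#: Wall regions distinguished by differential thickening.
REGIONS = (
    "lower periclinal",
    "upper periclinal ledge",
    "upper periclinal",
    "ventral",
    "dorsal",
)

#: Default per-region thickness table (μm). These are config placeholders for
#: the differential wall thickening of guard cells, not measured values;
#: replace with measured thicknesses when available.
DEFAULT_THICKNESS_UM = {
    "ventral": 1.0,
    "dorsal": 0.6,
    "upper periclinal ledge": 1.2,
    "upper periclinal": 0.8,
    "lower periclinal": 0.8,
}


@dataclass
class ThicknessTable:
    """Region → wall thickness (μm), with an optional longitudinal modulation.

    ``profile`` maps normalized arc position s ∈ [0, 1] along the guard-cell
    tube to a dimensionless scale factor. The default is flat (factor 1).
    """

    thickness: dict = field(default_factory=lambda: dict(DEFAULT_THICKNESS_UM))
    profile: object = None  # callable s -> factor, or None for flat

    def __post_init__(self):
        for region, t in self.thickness.items():
            if not (0.05 < t < 5):
                raise ValueError(f"thickness for {region!r} out of (0.05, 5) μm: {t}")

    @classmethod
    def uniform(cls, t: float) -> "ThicknessTable":
        return cls({r: t for r in REGIONS})

    def factor(self, s: float) -> float:
        return 1.0 if self.profile is None else float(self.profile(s))


@dataclass
class LandmarkSet:
    """Ordered closed 3D point loops along each guard-cell tube.

    ``rings`` maps cell_id (1 or 2) to a list of (k_i, 3) arrays ordered
    sequentially along the cell axis. ``junction_flags`` marks rings lying in
    the junction (pole) regions.
    """

    rings: dict
    junction_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        for cell_id, loops in self.rings.items():
            if cell_id not in (1, 2):
                raise ValueError(f"cell_id must be 1 or 2, got {cell_id}")
            if len(loops) < 8:
                raise ValueError(f"cell {cell_id}: need ≥8 rings, got {len(loops)}")
            for i, loop in enumerate(loops):
                if np.asarray(loop).shape[0] < 6:
                    raise ValueError(f"cell {cell_id} ring {i}: need ≥6 points")


@dataclass
class ShellMesh:
    """Triangulated mid-surface shell.

    nodes      : (n, 3) float, μm
    triangles  : (m, 3) int, outward-oriented (counter-clockwise seen from
                 outside)
    thickness  : (m,) float, μm per element
    region     : (m,) str labels from REGIONS ('' if unassigned)
    frame      : (m, 3, 3) float; frame[e] rows are (e1, e2, e3)
    node_sets  : named node-index sets (junction, dorsal, ventral, periclinal,
                 pore_rim, ...)
    rings      : optional dict cell_id -> (n_rings, n_per_ring) node-index
                 grid recording the tube structure the mesh was built from
    """

    nodes: np.ndarray
    triangles: np.ndarray
    thickness: np.ndarray = None
    region: np.ndarray = None
    frame: np.ndarray = None
    node_sets: dict = field(default_factory=dict)
    rings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        m = len(self.triangles)
        if self.thickness is None:
            self.thickness = np.full(m, 0.5)
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.region is None:
            self.region = np.full(m, "", dtype=object)
        if np.any(self.thickness <= 0):
            raise ValueError("element thickness must be > 0")

    # -- basic differential geometry -------------------------------------

    def tri_points(self) -> np.ndarray:
        return self.nodes[self.triangles]

    def normals(self, normalized: bool = True) -> np.ndarray:
        p = self.tri_points()
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        if normalized:
            n = n / np.linalg.norm(n, axis=1, keepdims=True)
        return n

    def areas(self) -> np.ndarray:
        p = self.tri_points()
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def centroids(self) -> np.ndarray:
        return self.tri_points().mean(axis=1)

    @property
    def total_area(self) -> float:
        return float(self.areas().sum())

    def edge_counts(self):
        e = np.sort(
            self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def is_watertight(self) -> bool:
        _, counts = self.edge_counts()
        return bool(np.all(counts == 2))

    def euler_characteristic(self) -> int:
        uniq, _ = self.edge_counts()
        return len(self.nodes) - len(uniq) + len(self.triangles)

    def enclosed_volume(self) -> float:
        p = self.tri_points()
        return float(np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6.0)

    def orient_outward(self) -> "ShellMesh":
        """Flip all triangles if the signed enclosed volume is negative."""
        if self.enclosed_volume() < 0:
            self.triangles = self.triangles[:, ::-1].copy()
        return self

    def copy(self) -> "ShellMesh":
        return dataclasses.replace(
            self,
            nodes=self.nodes.copy(),
            triangles=self.triangles.copy(),
            thickness=self.thickness.copy(),
            region=self.region.copy(),
            frame=None if self.frame is None else self.frame.copy(),
            node_sets={k: np.array(v) for k, v in self.node_sets.items()},
            rings={k: np.array(v) for k, v in self.rings.items()},
        )


# ---------------------------------------------------------------------------
# Ring splines and tube triangulation
# ---------------------------------------------------------------------------


def fit_ring_splines(ring: np.ndarray, smoothing: float = 0.0):
    """Fit a periodic parametric cubic spline through one closed 3D point loop.

    With ``smoothing == 0`` the spline interpolates the input points; larger
    values trade fidelity for smoothness (scipy ``splprep`` s parameter).
    Returns the spline representation (tck); evaluate with
    :func:`eval_ring_spline`.
    """
    ring = np.asarray(ring, dtype=float)
    if ring.shape[0] < 6:
        raise ValueError(f"need ≥6 points per ring, got {ring.shape[0]}")
    span = ring.max(axis=0) - ring.min(axis=0)
    # a closed loop must extend in at least two directions
    if np.sort(span)[-2] < 1e-9:
        raise ValueError("degenerate (colinear) ring")
    pts = ring.T
    tck, u_fit = splprep(pts, s=float(smoothing), per=1, k=3)
    return RingSpline(tck=tck, u_fit=np.asarray(u_fit))


@dataclass
class RingSpline:
    """Periodic parametric cubic spline of one ring; ``u_fit`` holds the
    (chord-length) parameter values of the fitted input points."""

    tck: object
    u_fit: np.ndarray


def eval_ring_spline(spline, u) -> np.ndarray:
    """Evaluate a ring spline at parameters ``u`` in [0, 1); returns (len(u), 3)."""
    tck = spline.tck if isinstance(spline, RingSpline) else spline
    return np.array(splev(np.asarray(u, dtype=float), tck)).T


def _align_ring(prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Cyclically shift ``cur`` to minimize twist against ``prev``.

    Minimal-twist vertex correspondence: choose the cyclic offset minimizing
    the total squared distance between corresponding vertices.
    """
    n = len(cur)
    best, best_cost = 0, np.inf
    for off in range(n):
        cost = np.sum((np.roll(cur, -off, axis=0) - prev) ** 2)
        if cost < best_cost:
            best, best_cost = off, cost
    return np.roll(cur, -best, axis=0)


def resample_and_triangulate(
    splines,
    n_per_ring: int,
    closed: bool = False,
    cap_ends: bool = False,
    align: bool = True,
) -> ShellMesh:
    """Resample ring splines and join consecutive rings by triangle strips.

    Each ring contributes ``n_per_ring`` vertices at equal parameter spacing;
    consecutive rings are connected by 2·n_per_ring triangles with
    minimal-twist correspondence. ``closed`` joins the last ring back to the
    first (torus topology, Euler characteristic 0); ``cap_ends`` adds
    triangle fans over the two open ends (Euler characteristic 2).
    """
    if len(splines) < 2:
        raise ValueError("need ≥2 rings")
    u = np.arange(n_per_ring) / n_per_ring
    rings = [eval_ring_spline(tck, u) for tck in splines]
    if align:
        for i in range(1, len(rings)):
            rings[i] = _align_ring(rings[i - 1], rings[i])
    return triangulate_ring_grid(np.array(rings), closed=closed, cap_ends=cap_ends)


def triangulate_ring_grid(
    ring_pts: np.ndarray, closed: bool = False, cap_ends: bool = False
) -> ShellMesh:
    """Triangulate an (n_rings, n_per_ring, 3) grid of tube vertices."""
    n_r, n_p, _ = ring_pts.shape
    nodes = ring_pts.reshape(-1, 3)
    idx = np.arange(n_r * n_p).reshape(n_r, n_p)
    tris = []
    last = n_r if closed else n_r - 1
    for i in range(last):
        a = idx[i]
        b = idx[(i + 1) % n_r]
        for j in range(n_p):
            j2 = (j + 1) % n_p
            # alternate the quad diagonal (union-jack pattern) so the
            # triangulation carries the mirror symmetries of the tube
            if (i + j) % 2 == 0:
                tris.append((a[j], b[j], b[j2]))
                tris.append((a[j], b[j2], a[j2]))
            else:
                tris.append((a[j], b[j], a[j2]))
                tris.append((b[j], b[j2], a[j2]))
    if cap_ends and not closed:
        # fan caps over the two boundary rings
        for ring, flip in ((idx[0], True), (idx[-1], False)):
            c = len(nodes)
            nodes = np.vstack([nodes, ring_pts.reshape(-1, 3)[ring].mean(axis=0)])
            for j in range(n_p):
                j2 = (j + 1) % n_p
                tri = (c, ring[j], ring[j2]) if not flip else (c, ring[j2], ring[j])
                tris.append(tri)
    mesh = ShellMesh(nodes=np.asarray(nodes), triangles=np.array(tris, dtype=int))
    mesh.rings = {1: idx}
    mesh.orient_outward()
    _check_self_intersection(mesh, ring_pts, closed)
    return mesh


def _check_self_intersection(mesh: ShellMesh, ring_pts: np.ndarray, closed: bool):
    """Cheap tube self-intersection guard: consecutive cross-sections whose
    centroid spacing is smaller than the local collapse of the strip indicate
    an inverted segment."""
    cent = ring_pts.mean(axis=1)
    n_r = len(cent)
    last = n_r if closed else n_r - 1
    for i in range(last):
        nxt = (i + 1) % n_r
        step = cent[nxt] - cent[i]
        d = np.linalg.norm(step)
        if d < 1e-12:
            raise ValueError(f"self-intersecting tube between rings {i} and {nxt}")
        # the next section must lie ahead of the previous one on average;
        # a negative mean projection means the sweep folded back on itself
        proj = (ring_pts[nxt] - cent[i]) @ (step / d)
        if proj.mean() < 0:
            raise ValueError(f"self-intersecting tube between rings {i} and {nxt}")
        # a sweep reversal (>90° turn between consecutive steps) folds the
        # strip through itself
        nxt2 = (nxt + 1) % n_r
        if nxt2 != i and (closed or nxt < last):
            step2 = cent[nxt2] - cent[nxt]
            if step2 @ step < 0:
                raise ValueError(
                    f"self-intersecting tube between rings {i} and {nxt2}")


# ---------------------------------------------------------------------------
# Frames, regions, thickness
# ---------------------------------------------------------------------------


def assign_material_frames(mesh: ShellMesh) -> ShellMesh:
    """Assign per-element orthonormal material frames.

    e1 follows the tube axis (longitudinal/polar), e2 = e3 × e1 is the hoop
    (circumferential, cellulose-microfibril) direction, e3 is the outward
    normal. The longitudinal direction is taken from the ring structure where
    available; meshes without ring structure (e.g. spheres used in
    verification) get an arbitrary smooth tangent for e1.
    """
    normals = mesh.normals()
    m = len(mesh.triangles)
    frame = np.empty((m, 3, 3))
    axis_dir = np.zeros((len(mesh.nodes), 3))
    have_axis = np.zeros(len(mesh.nodes), dtype=bool)
    for idx in mesh.rings.values():
        idx = np.asarray(idx)
        n_r = idx.shape[0]
        cent = mesh.nodes[idx].mean(axis=1)
        spacing = np.linalg.norm(np.diff(cent, axis=0), axis=1).mean()
        closed = np.linalg.norm(cent[0] - cent[-1]) <= 2.0 * spacing
        for i in range(n_r):
            if closed:
                i0, i1 = (i - 1) % n_r, (i + 1) % n_r
            else:  # one-sided differences at open tube ends
                i0, i1 = max(i - 1, 0), min(i + 1, n_r - 1)
            d = mesh.nodes[idx[i1]] - mesh.nodes[idx[i0]]
            axis_dir[idx[i]] = d
            have_axis[idx[i]] = True
    for e in range(m):
        n = normals[e]
        tri = mesh.triangles[e]
        if have_axis[tri].any():
            t = axis_dir[tri][have_axis[tri]].mean(axis=0)
        else:
            t = np.array([1.0, 0.0, 0.0])
        # project tangent into the element plane
        t = t - (t @ n) * n
        if np.linalg.norm(t) < 1e-12:
            t = np.array([0.0, 1.0, 0.0]) - n[1] * n
        e1 = t / np.linalg.norm(t)
        e2 = np.cross(n, e1)
        frame[e, 0], frame[e, 1], frame[e, 2] = e1, e2, n
    mesh.frame = frame
    return mesh


def _hoop_angles(mesh: ShellMesh) -> np.ndarray:
    """Hoop angle ψ of each element around its local tube cross-section.

    ψ = 0 on the dorsal (outward-facing) equator, ±π on the ventral
    (pore-facing) side, +π/2 on the upper periclinal surface. Derived from
    the outward normal: its vertical component against its horizontal
    component along the direction away from the complex center.
    """
    if mesh.frame is None:
        assign_material_frames(mesh)
    center = mesh.nodes.mean(axis=0)
    cent = mesh.centroids()
    e3 = mesh.frame[:, 2]
    r = cent - center
    r[:, 2] = 0.0
    nrm = np.linalg.norm(r, axis=1)
    nrm[nrm < 1e-12] = 1.0
    r /= nrm[:, None]
    s = np.einsum("ij,ij->i", e3, r)  # + on dorsal side, − on ventral
    return np.arctan2(e3[:, 2], s)


def assign_regions_and_thickness(
    mesh: ShellMesh, table: ThicknessTable | None = None
) -> ShellMesh:
    """Label each element with its wall region and assign thickness.

    Region classification is geometric: by the hoop angle of the outward
    normal around the tube cross-section (dorsal faces away from the pore,
    ventral toward it, periclinal up/down; the upper periclinal ledge is the
    pore-side shoulder of the top surface). Thickness is the table value
    scaled by the longitudinal modulation factor at the element centroid.
    """
    if table is None:
        table = ThicknessTable()
    for region in REGIONS:
        if region not in table.thickness:
            raise KeyError(f"thickness table missing region {region!r}")
    psi = np.degrees(_hoop_angles(mesh))
    region = np.empty(len(mesh.triangles), dtype=object)
    region[:] = "dorsal"
    region[np.abs(psi) >= 130] = "ventral"
    region[(psi > 50) & (psi <= 105)] = "upper periclinal"
    region[(psi > 105) & (psi < 130)] = "upper periclinal ledge"
    region[(psi < -50) & (psi > -130)] = "lower periclinal"
    mesh.region = region

    s = _longitudinal_positions(mesh)
    thick = np.array([table.thickness[r] for r in region], dtype=float)
    thick *= np.array([table.factor(si) for si in s])
    mesh.thickness = thick
    return mesh


def _longitudinal_positions(mesh: ShellMesh) -> np.ndarray:
    """Normalized arc position s ∈ [0, 1] of each element along its tube."""
    m = len(mesh.triangles)
    s_node = np.zeros(len(mesh.nodes))
    for idx in mesh.rings.values():
        idx = np.asarray(idx)
        n_r = idx.shape[0]
        s_ring = np.arange(n_r) / max(n_r - 1, 1)
        for i in range(n_r):
            s_node[idx[i]] = s_ring[i]
    cent_s = s_node[mesh.triangles].mean(axis=1)
    return cent_s if m else np.zeros(0)


# ---------------------------------------------------------------------------
# Landmark CSV I/O and mesh export
# ---------------------------------------------------------------------------

LANDMARK_COLUMNS = ["cell_id", "ring_index", "point_index", "x", "y", "z"]


def export_landmarks(landmarks: LandmarkSet, path) -> None:
    rows = []
    for cell_id in sorted(landmarks.rings):
        for ri, ring in enumerate(landmarks.rings[cell_id]):
            for pi, (x, y, z) in enumerate(np.asarray(ring, dtype=float)):
                rows.append((cell_id, ri, pi, x, y, z))
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def import_landmarks(path) -> LandmarkSet:
    """Read a landmark-ring CSV (cell_id, ring_index, point_index, x, y, z; μm)."""
    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rings: dict = {}
    for cell_id, cell_df in df.groupby("cell_id"):
        ring_ids = cell_df["ring_index"].to_numpy()
        expected = np.arange(cell_df["ring_index"].nunique())
        seen = np.unique(ring_ids)
        ordered = np.all(np.diff(ring_ids) >= 0)
        if not (np.array_equal(seen, expected) and ordered):
            row = int(cell_df.index[np.argmin(np.diff(ring_ids) >= 0)] + 2) if not ordered else int(cell_df.index[0]) + 2
            raise ValueError(
                f"{path}: cell {cell_id} ring indices not sequential from 0 "
                f"(near row {row})"
            )
        loops = []
        for ri, ring_df in cell_df.groupby("ring_index"):
            order = ring_df["point_index"].to_numpy()
            if not np.array_equal(order, np.arange(len(order))):
                bad = int(ring_df.index[0]) + 2
                raise ValueError(
                    f"{path}: cell {cell_id} ring {ri}: point indices out of "
                    f"order (near row {bad})"
                )
            loops.append(ring_df[["x", "y", "z"]].to_numpy(dtype=float))
        rings[int(cell_id)] = loops
    return LandmarkSet(rings=rings)


def export_mesh(mesh: ShellMesh, path) -> None:
    """Write a shell mesh as a legacy VTK unstructured grid with thickness,
    region codes, and material-frame vectors as cell data."""
    cell_scalars = {"thickness": mesh.thickness, "region": mesh.region}
    cell_vectors = {}
    if mesh.frame is not None:
        cell_vectors = {
            "e1": mesh.frame[:, 0],
            "e2": mesh.frame[:, 1],
            "e3": mesh.frame[:, 2],
        }
    _vtk.write_vtk(path, mesh.nodes, mesh.triangles, cell_scalars, cell_vectors)


def import_mesh(path) -> ShellMesh:
    nodes, triangles = _vtk.read_vtk(path)
    return ShellMesh(nodes=nodes, triangles=triangles)


def weld_junctions(mesh: ShellMesh, tol: float = 0.2) -> ShellMesh:
    """Merge coincident nodes across the two cells (nearest-point welding
    within ``tol`` μm) and record the merged set as the junction node set."""
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.nodes)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(mesh.nodes))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    root = np.array([find(i) for i in range(len(mesh.nodes))])
    uniq, inv = np.unique(root, return_inverse=True)
    new_nodes = np.zeros((len(uniq), 3))
    np.add.at(new_nodes, inv, mesh.nodes)
    counts = np.bincount(inv).astype(float)
    new_nodes /= counts[:, None]
    mesh.nodes = new_nodes
    mesh.triangles = inv[mesh.triangles]
    mesh.rings = {cid: inv[np.asarray(idx)] for cid, idx in mesh.rings.items()}
    mesh.node_sets = {k: np.unique(inv[np.asarray(v)]) for k, v in mesh.node_sets.items()}
    welded = np.where(counts > 1)[0]
    mesh.node_sets["junction"] = np.union1d(
        mesh.node_sets.get("junction", np.array([], dtype=int)), welded
    )
    return mesh


def landmarks_to_mesh(
    landmarks: LandmarkSet,
    n_per_ring: int = 24,
    smoothing: float = 0.0,
    thickness_table: ThicknessTable | None = None,
    weld_tol: float = 0.2,
) -> ShellMesh:
    """Full meshing pipeline: ring splines → strips → weld → regions/frames."""
    meshes = []
    for cell_id in sorted(landmarks.rings):
        splines = [fit_ring_splines(r, smoothing) for r in landmarks.rings[cell_id]]
        meshes.append((cell_id, resample_and_triangulate(splines, n_per_ring, cap_ends=True)))
    # concatenate
    all_nodes, all_tris, rings = [], [], {}
    offset = 0
    for cell_id, m in meshes:
        all_nodes.append(m.nodes)
        all_tris.append(m.triangles + offset)
        rings[cell_id] = np.asarray(m.rings[1]) + offset
        offset += len(m.nodes)
    mesh = ShellMesh(nodes=np.vstack(all_nodes), triangles=np.vstack(all_tris))
    mesh.rings = rings
    if len(meshes) > 1:
        weld_junctions(mesh, weld_tol)
    assign_material_frames(mesh)
    assign_regions_and_thickness(mesh, thickness_table)
    return mesh
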