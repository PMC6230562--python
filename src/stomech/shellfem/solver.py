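"""Incremental Newton solution of turgor-pressurized guard-cell shells.

Loading is ramped in increments; within each increment the residual
(internal force minus follower-pressure load) is driven to zero by Newton
iteration with a backtracking line search. Pavement-cell support is modeled
either as none (free complex, grounded by a statically determinate 3-2-1
support that carries no load) or as prescribed displacements driving the
complex length/width to experimentally observed open-state targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..meshing import ShellMesh, assign_material_frames
from .material import OrthotropicMaterial
from . import _kernels


@dataclass
class LoadCase:
    """Turgor pressure (MPa) plus the pavement-cell constraint mode.

    ``constraint_mode`` is "none" (free pressurization) or "complex-dims"
    (displacement boundary conditions ramp the junction and dorsal node sets
    so the deformed complex length/width reach the given targets, μm).
    """

    turgor: float = 5.0
    constraint_mode: str = "none"
    target_complex_length: float | None = None
    target_complex_width: float | None = None

    def __post_init__(self):
        if self.turgor < 0:
            raise ValueError("turgor must be ≥ 0")
        if self.constraint_mode not in ("none", "complex-dims"):
            raise ValueError(f"unknown constraint_mode {self.constraint_mode!r}")
        if self.constraint_mode == "complex-dims":
            if self.target_complex_length is None or self.target_complex_width is None:
                raise ValueError("complex-dims constraints need both targets")


@dataclass
class SolverSettings:
    n_increments: int = 10
    newton_tol: float = 1e-6
    max_iterations: int = 30

    def __post_init__(self):
        if self.n_increments < 1:
            raise ValueError("n_increments must be ≥ 1")
        if not (0 < self.newton_tol <= 1e-2):
            raise ValueError("newton_tol must lie in (0, 1e-2]")


@dataclass
class SimulationResult:
    displacements: np.ndarray          # (n, 3) μm
    converged: bool
    increments_completed: int
    strain: np.ndarray = None          # (m, 3) Green strain, material frame
    stress: np.ndarray = None          # (m, 3) 2nd PK stress, MPa
    reactions: np.ndarray = None       # (n, 3) constraint forces, μN
    junction_loading: float = 0.0      # MPa
    dorsal_loading: float = 0.0        # MPa
    strain_energy: float = 0.0         # μN·μm = pJ
    external_work: float = 0.0
    residual_history: list = field(default_factory=list)
    deformed_geometry: object = None   # StomatalGeometry, filled by measure
    constraint_mode: str = "none"
    constrained_sets: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Discretization setup
# ---------------------------------------------------------------------------


def _element_bases(mesh: ShellMesh):
    """Per-element reference basis (a1 along material e1, a2 = n×a1) and the
    2D reference edge matrix inverse."""
    if mesh.frame is None:
        assign_material_frames(mesh)
    p = mesh.tri_points()
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    areas = 0.5 * np.linalg.norm(n, axis=1)
    if np.any(areas < 1e-12):
        bad = int(np.argmin(areas))
        raise ValueError(f"degenerate (zero-area) element {bad}")
    n_hat = n / (2 * areas)[:, None]
    a1 = mesh.frame[:, 0].copy()
    a1 -= np.einsum("ij,ij->i", a1, n_hat)[:, None] * n_hat
    nrm = np.linalg.norm(a1, axis=1)
    low = nrm < 1e-8
    if low.any():  # frame degenerate for this facet; any tangent will do
        alt = np.cross(n_hat[low], np.array([0.0, 0.0, 1.0]))
        alt_n = np.linalg.norm(alt, axis=1)
        fix = alt_n < 1e-8
        alt[fix] = np.cross(n_hat[low][fix], np.array([1.0, 0.0, 0.0]))
        a1[low] = alt
        nrm = np.linalg.norm(a1, axis=1)
    a1 /= nrm[:, None]
    a2 = np.cross(n_hat, a1)
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    dm = np.empty((len(p), 2, 2))
    dm[:, 0, 0] = np.einsum("ij,ij->i", e1, a1)
    dm[:, 0, 1] = np.einsum("ij,ij->i", e2, a1)
    dm[:, 1, 0] = np.einsum("ij,ij->i", e1, a2)
    dm[:, 1, 1] = np.einsum("ij,ij->i", e2, a2)
    det = dm[:, 0, 0] * dm[:, 1, 1] - dm[:, 0, 1] * dm[:, 1, 0]
    dminv = np.empty_like(dm)
    dminv[:, 0, 0] = dm[:, 1, 1] / det
    dminv[:, 1, 1] = dm[:, 0, 0] / det
    dminv[:, 0, 1] = -dm[:, 0, 1] / det
    dminv[:, 1, 0] = -dm[:, 1, 0] / det
    return a1, a2, n_hat, areas, dminv


def _build_hinges(mesh: ShellMesh):
    """Interior-edge hinges (i, j, k, l): edge i–j shared by triangles
    (i, j, k) and (j, i, l) in consistent orientation."""
    edge_map = {}
    tris = mesh.triangles
    for e in range(len(tris)):
        for a in range(3):
            i, j = int(tris[e, a]), int(tris[e, (a + 1) % 3])
            k = int(tris[e, (a + 2) % 3])
            edge_map[(i, j)] = (e, k)
    hinges, pairs = [], []
    for (i, j), (e1, k) in edge_map.items():
        if i < j and (j, i) in edge_map:
            e2, l = edge_map[(j, i)]
            hinges.append((i, j, k, l))
            pairs.append((e1, e2))
    return (np.array(hinges, dtype=np.int64).reshape(-1, 4),
            np.array(pairs, dtype=np.int64).reshape(-1, 2))


def hinge_bending_stiffness(material: OrthotropicMaterial, thickness: float,
                            edge_len: float, area_sum: float,
                            angle: float = 0.0) -> float:
    """Hinge constant k (μN·μm) carrying the plate flexural rigidity
    D = E(φ)·t³/12 of the adjacent elements: k = D·|e|²/(A1+A2)."""
    D = material.bending_modulus(angle) * thickness**3 / 12.0
    return D * edge_len**2 / area_sum


class _FEModel:
    """Assembled discrete model: element data, hinges, constraint pattern."""

    def __init__(self, mesh: ShellMesh, material: OrthotropicMaterial):
        self.mesh = mesh
        self.material = material
        a1, a2, n_hat, areas, dminv = _element_bases(mesh)
        self.areas = areas
        self.dminv = np.ascontiguousarray(dminv)
        q = material.plane_stress_Q()
        self.q = np.ascontiguousarray(np.broadcast_to(q, (len(areas), 3, 3)).copy())
        self.ta = np.ascontiguousarray(mesh.thickness * areas)
        hinges, pairs = _build_hinges(mesh)
        self.hinges = hinges
        x0 = mesh.nodes
        kb = np.zeros(len(hinges))
        th0 = np.zeros(len(hinges))
        for h in range(len(hinges)):
            i, j, k, l = hinges[h]
            e1, e2 = pairs[h]
            edge = x0[j] - x0[i]
            le = np.linalg.norm(edge)
            # bending direction ⊥ edge in the surface; its angle from the
            # material 1-axis sets the effective bending modulus
            nav = n_hat[e1] + n_hat[e2]
            nav /= max(np.linalg.norm(nav), 1e-12)
            b = np.cross(edge / le, nav)
            c1 = abs(b @ mesh.frame[e1, 0])
            s1 = abs(b @ mesh.frame[e1, 1])
            ang = np.arctan2(s1, c1)
            t_avg = 0.5 * (mesh.thickness[e1] + mesh.thickness[e2])
            kb[h] = hinge_bending_stiffness(
                material, t_avg, le, areas[e1] + areas[e2], ang)
            th0[h] = _kernels._dihedral(x0[i], x0[j], x0[k], x0[l])
        self.kb = kb
        self.th0 = th0
        nnz = 81 * len(areas) + 144 * len(hinges)
        self._rows = np.empty(nnz, dtype=np.int64)
        self._cols = np.empty(nnz, dtype=np.int64)
        self._vals = np.empty(nnz)

    def forces(self, x, p):
        return _kernels.assemble_forces(
            x, self.mesh.triangles, self.dminv, self.q, self.ta,
            self.hinges, self.kb, self.th0, p)

    def tangent(self, x, p):
        n = _kernels.assemble_tangent(
            x, self.mesh.triangles, self.dminv, self.q, self.ta,
            self.hinges, self.kb, self.th0, p,
            self._rows, self._cols, self._vals)
        ndof = 3 * len(self.mesh.nodes)
        K = sp.coo_matrix(
            (self._vals[:n], (self._rows[:n], self._cols[:n])),
            shape=(ndof, ndof)).tocsr()
        return K


# ---------------------------------------------------------------------------
# Boundary conditions
# ---------------------------------------------------------------------------


def _rigid_modes(nodes):
    n = len(nodes)
    c = nodes.mean(axis=0)
    modes = np.zeros((6, n, 3))
    modes[0, :, 0] = 1
    modes[1, :, 1] = 1
    modes[2, :, 2] = 1
    r = nodes - c
    modes[3, :, 1], modes[3, :, 2] = -r[:, 2], r[:, 1]
    modes[4, :, 0], modes[4, :, 2] = r[:, 2], -r[:, 0]
    modes[5, :, 0], modes[5, :, 1] = -r[:, 1], r[:, 0]
    return modes.reshape(6, -1)


def _auto_ground(nodes) -> list:
    """Statically determinate 3-2-1 support: six (node, component) pairs that
    restrain all rigid-body modes. Balanced loads put zero force through
    them, so the elastic solution is unperturbed."""
    c = nodes.mean(axis=0)
    i0 = int(np.argmax(np.linalg.norm(nodes - c, axis=1)))
    d = np.linalg.norm(nodes - nodes[i0], axis=1)
    i1 = int(np.argmax(d))
    axis = nodes[i1] - nodes[i0]
    axis /= np.linalg.norm(axis)
    # farthest node from the i0–i1 line
    rel = nodes - nodes[i0]
    perp = rel - np.outer(rel @ axis, axis)
    i2 = int(np.argmax(np.linalg.norm(perp, axis=1)))
    comps1 = list(np.argsort(np.abs(axis))[:2])
    plane_n = np.cross(axis, perp[i2] / np.linalg.norm(perp[i2]))
    comp2 = int(np.argmax(np.abs(plane_n)))
    constraints = ([(i0, 0), (i0, 1), (i0, 2)]
                   + [(i1, int(cmp)) for cmp in comps1] + [(i2, comp2)])
    # verify the six constraints restrain all six rigid modes
    modes = _rigid_modes(nodes)
    mat = np.array([modes[:, 3 * n + cmp] for n, cmp in constraints])
    if np.linalg.matrix_rank(mat, tol=1e-8) < 6:
        # fall back: add z of another extreme node (rare degenerate layouts)
        i3 = int(np.argmax(np.abs(nodes[:, 2])))
        constraints[-1] = (i3, 2)
    return constraints


def _complex_dims_bcs(mesh: ShellMesh, loadcase: LoadCase):
    """Prescribed displacements emulating pavement-cell support.

    Junction nodes are driven along the pore axis (x) so the deformed
    complex length reaches its target, and held vertically; dorsal flank
    nodes are driven laterally (y) to the target complex width. A few
    symmetry-point supports remove the remaining rigid modes.
    """
    for req in ("junction", "dorsal"):
        if req not in mesh.node_sets:
            raise ValueError(f"complex-dims constraints need node set {req!r}")
    nodes = mesh.nodes
    length = nodes[:, 0].max() - nodes[:, 0].min()
    width = nodes[:, 1].max() - nodes[:, 1].min()
    dL = (loadcase.target_complex_length - length) / 2.0
    dW = (loadcase.target_complex_width - width) / 2.0
    fixed = np.zeros((len(nodes), 3), dtype=bool)
    target = np.zeros((len(nodes), 3))
    jn = np.asarray(mesh.node_sets["junction"])
    fixed[jn, 0] = True
    target[jn, 0] = np.sign(nodes[jn, 0]) * dL
    fixed[jn, 2] = True
    dorsal = np.asarray(mesh.node_sets["dorsal"])
    flank = dorsal[np.abs(nodes[dorsal, 1]) > 0.5 * width / 2.0]
    fixed[flank, 1] = True
    target[flank, 1] = np.sign(nodes[flank, 1]) * dW
    # rigid-mode clean-up at symmetry points (zero-motion by symmetry)
    jx = jn[np.argmax(nodes[jn, 0])]
    jx2 = jn[np.argmin(nodes[jn, 0])]
    fixed[jx, 1] = fixed[jx2, 1] = True
    fy = flank[np.argmax(nodes[flank, 1])]
    fixed[fy, 2] = True
    sets = {"junction": jn, "dorsal": flank}
    return fixed, target, sets


# ---------------------------------------------------------------------------
# Nonlinear solve
# ---------------------------------------------------------------------------


def solve_nonlinear(
    mesh: ShellMesh,
    material: OrthotropicMaterial,
    loadcase: LoadCase | None = None,
    settings: SolverSettings | None = None,
    measure: bool = True,
    fixed_nodes=None,
) -> SimulationResult:
    """Simulate turgor-driven deformation of a guard-cell shell mesh.

    Pressure (and any prescribed displacement) ramps linearly over
    ``settings.n_increments``; each increment is equilibrated by Newton
    iteration with element-wise finite-difference consistent tangents and a
    backtracking line search. On divergence the last equilibrated state is
    returned with ``converged=False``.

    ``fixed_nodes`` optionally clamps the listed node indices (all three
    components) instead of the automatic statically determinate support.
    """
    if loadcase is None:
        loadcase = LoadCase()
    if settings is None:
        settings = SolverSettings()
    model = _FEModel(mesh, material)
    nodes = mesh.nodes
    n = len(nodes)

    if loadcase.constraint_mode == "complex-dims":
        fixed, target, sets = _complex_dims_bcs(mesh, loadcase)
    elif fixed_nodes is not None:
        fixed = np.zeros((n, 3), dtype=bool)
        fixed[np.asarray(fixed_nodes, dtype=int)] = True
        target = np.zeros((n, 3))
        sets = {}
    else:
        fixed = np.zeros((n, 3), dtype=bool)
        target = np.zeros((n, 3))
        for ni, cmp in _auto_ground(nodes):
            fixed[ni, cmp] = True
        sets = {}
    free = ~fixed.reshape(-1)

    u = np.zeros((n, 3))
    u_ok = u.copy()
    hist = []
    converged_all = True
    inc_done = 0
    work = 0.0
    fext_prev = np.zeros((n, 3))
    u_prev = np.zeros((n, 3))

    for inc in range(1, settings.n_increments + 1):
        lam = inc / settings.n_increments
        p = lam * loadcase.turgor
        u[fixed] = (lam * target)[fixed]
        ok = False
        for it in range(settings.max_iterations):
            x = nodes + u
            fint, fext, _ = model.forces(x, p)
            resid = (fint - fext).reshape(-1)
            rn = np.abs(resid[free]).max() if free.any() else 0.0
            scale = max(np.abs(fext).max(), np.abs(fint).max(), 1e-9)
            hist.append((inc, it, rn))
            if rn <= max(settings.newton_tol * scale, 1e-10):
                ok = True
                break
            K = model.tangent(x, p)
            Kff = K[free][:, free]
            try:
                du = spla.spsolve(Kff.tocsc(), -resid[free])
            except Exception:
                du = np.full(free.sum(), np.nan)
            if not np.all(np.isfinite(du)):
                break
            # backtracking line search on the residual norm
            alpha, best_alpha, best_rn = 1.0, 0.0, rn
            for _ in range(10):
                u_try = u.reshape(-1).copy()
                u_try[free] += alpha * du
                fi, fe, _ = model.forces(nodes + u_try.reshape(n, 3), p)
                r_try = np.abs((fi - fe).reshape(-1)[free]).max()
                if np.isfinite(r_try) and r_try < best_rn:
                    best_rn, best_alpha = r_try, alpha
                if np.isfinite(r_try) and r_try < 0.5 * rn:
                    break
                alpha *= 0.5
            if best_alpha == 0.0:
                break
            u.reshape(-1)[free] += best_alpha * du
        if not ok:
            converged_all = False
            u = u_ok
            break
        # trapezoidal external work accumulation (pressure part)
        x = nodes + u
        _, fext, _ = model.forces(x, p)
        work += 0.5 * float(np.sum((fext + fext_prev) * (u - u_prev)))
        fext_prev, u_prev = fext, u.copy()
        u_ok = u.copy()
        inc_done = inc

    x = nodes + u
    p_final = (inc_done / settings.n_increments) * loadcase.turgor
    fint, fext, energy = model.forces(x, p_final)
    strain, stress = _kernels.membrane_strain_stress(
        x, mesh.triangles, model.dminv, model.q)
    reactions = np.where(fixed, fint - fext, 0.0)

    result = SimulationResult(
        displacements=u,
        converged=converged_all,
        increments_completed=inc_done,
        strain=strain,
        stress=stress,
        reactions=reactions,
        strain_energy=energy,
        external_work=work,
        residual_history=hist,
        constraint_mode=loadcase.constraint_mode,
        constrained_sets=sets,
    )
    if loadcase.constraint_mode == "complex-dims":
        jl, dl = reaction_loadings(result, mesh)
        result.junction_loading, result.dorsal_loading = jl, dl
    if measure:
        from .measure import measure_model_geometry
        try:
            result.deformed_geometry = measure_model_geometry(result, mesh)
        except ValueError:
            result.deformed_geometry = None
    return result


def _set_area(mesh: ShellMesh, node_set) -> float:
    """Mid-surface area attributed to a node set (per-node share of element
    areas)."""
    node_set = set(int(i) for i in np.asarray(node_set))
    areas = mesh.areas()
    total = 0.0
    for e, tri in enumerate(mesh.triangles):
        inside = sum(1 for v in tri if int(v) in node_set)
        total += areas[e] * inside / 3.0
    return total


def reaction_loadings(result: SimulationResult, mesh: ShellMesh):
    """Additional loadings (MPa) exerted by neighboring cells at the junction
    and dorsal regions, from the constraint reactions.

    Sign convention: positive = compressive support (neighbors push the
    guard cells inward against their outward expansion).
    """
    if result.constraint_mode != "complex-dims" or not result.constrained_sets:
        return 0.0, 0.0
    nodes = mesh.nodes
    out = []
    for name, comp in (("junction", 0), ("dorsal", 1)):
        ns = np.asarray(result.constrained_sets[name])
        sgn = np.sign(nodes[ns, comp])
        force_out = float(np.sum(sgn * result.reactions[ns, comp]))
        area = _set_area(mesh, ns)
        out.append(-force_out / max(area, 1e-12))
    return tuple(out)


# ---------------------------------------------------------------------------
# Linear element stiffness (analytic; verification surface)
# ---------------------------------------------------------------------------


def element_stiffness(
    element: np.ndarray,
    material: OrthotropicMaterial,
    thickness: float,
    frame: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic linear membrane stiffness (9×9, μN/μm) of one flat triangle.

    ``element`` is (3, 3) node coordinates; ``frame`` the material triad
    (rows e1, e2, e3; default: e1 along the first edge). The matrix is
    symmetric positive-semidefinite with exactly six zero-energy (rigid-body
    and out-of-plane) modes; bending stiffness lives on the hinges between
    elements (see :func:`hinge_bending_stiffness`), so no drilling
    stabilization is needed in this translational-DOF formulation.
    """
    element = np.asarray(element, dtype=float)
    e1 = element[1] - element[0]
    e2 = element[2] - element[0]
    nvec = np.cross(e1, e2)
    area = 0.5 * np.linalg.norm(nvec)
    if area < 1e-12:
        raise ValueError("zero-area element")
    n_hat = nvec / (2 * area)
    if frame is None:
        a1 = e1 / np.linalg.norm(e1)
    else:
        a1 = np.asarray(frame[0], dtype=float)
        a1 = a1 - (a1 @ n_hat) * n_hat
        a1 /= np.linalg.norm(a1)
    a2 = np.cross(n_hat, a1)
    dm = np.array([[e1 @ a1, e2 @ a1], [e1 @ a2, e2 @ a2]])
    dminv = np.linalg.inv(dm)
    # B maps the 9 nodal displacement components to (ε11, ε22, γ12)
    B = np.zeros((3, 9))
    for col in range(9):
        node, d = divmod(col, 3)
        dd = np.zeros((3, 2))
        if node == 1:
            dd[d, 0] = 1.0
        elif node == 2:
            dd[d, 1] = 1.0
        else:
            dd[d, 0] = dd[d, 1] = -1.0
        dF = dd @ dminv  # (3, 2) in global comps
        g1, g2 = dF.T @ a1, dF.T @ a2  # rows of projected gradient
        B[0, col] = g1[0]
        B[1, col] = g2[1]
        B[2, col] = g1[1] + g2[0]
    Q = material.plane_stress_Q()
    return thickness * area * B.T @ Q @ B
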