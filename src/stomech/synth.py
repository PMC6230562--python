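"""Synthetic stomatal complexes with known ground truth.

Generates (a) parametric mid-surface shell meshes of a guard-cell pair as an
elliptical torus around an elliptical pore, (b) confocal-like 3D image stacks
of propidium-iodide-style wall staining (bright wall shells of two contacting
bent tubes, degraded by PSF blur and additive noise), and (c) per-genotype
geometry tables sampled around published means/SEs — so every downstream
stage is testable without any real micrograph.

Geometry convention. The five nominal dimensions (pore width/length, complex
length/width, guard-cell width) over-determine a torus, because real
measurement tables carry noise. The generators prioritize the pore and
complex dimensions (four constraints fixing the pore-side and outer-side
ellipses); the guard-cell width sets the out-of-plane tube semi-axis. The
mesh generator interprets the dimensions as *mid-surface* geometry (what an
FE shell is built on); the stack generator renders the wall band so that the
*visible* stained geometry — the aperture between lumen-side faces, the
outer extent of the bright walls — equals the nominal dimensions, matching
how each artifact is measured downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .units import PIXEL_SIZE_UM, Z_STEP_UM
from .meshing import (
    ShellMesh,
    ThicknessTable,
    LandmarkSet,
    triangulate_ring_grid,
    assign_material_frames,
    assign_regions_and_thickness,
)

#: Published per-genotype geometry (mean ± SE, μm or μm²) for closed and open
#: states: (pore_width, pore_length, aspect_ratio, pore_area, complex_length,
#: complex_width, junction_area, guard_cell_width, guard_cell_arc_length).
PUBLISHED_GEOMETRY = {
    ("closed", "Col-0"): {
        "pore_width": (1.2, 0.1), "pore_length": (11.9, 0.4),
        "aspect_ratio": (0.10, 0.01), "pore_area": (12.6, 1.1),
        "complex_length": (24.5, 0.5), "complex_width": (14.8, 0.3),
        "junction_area": (49.9, 1.6), "guard_cell_width": (6.5, 0.2),
        "guard_cell_arc_length": (20.7, 0.4),
    },
    ("closed", "cesa3je5"): {
        "pore_width": (2.5, 0.2), "pore_length": (11.2, 0.4),
        "aspect_ratio": (0.23, 0.01), "pore_area": (24.6, 1.6),
        "complex_length": (22.9, 0.5), "complex_width": (15.2, 0.4),
        "junction_area": (46.6, 1.3), "guard_cell_width": (6.2, 0.2),
        "guard_cell_arc_length": (22.6, 0.6),
    },
    ("closed", "xxt1xxt2"): {
        "pore_width": (0.6, 0.1), "pore_length": (12.2, 0.4),
        "aspect_ratio": (0.05, 0.01), "pore_area": (7.1, 1.0),
        "complex_length": (24.8, 0.5), "complex_width": (14.4, 0.2),
        "junction_area": (46.1, 0.9), "guard_cell_width": (6.3, 0.2),
        "guard_cell_arc_length": (19.7, 0.3),
    },
    ("closed", "PGX1OE"): {
        "pore_width": (0.7, 0.1), "pore_length": (12.4, 0.3),
        "aspect_ratio": (0.06, 0.01), "pore_area": (10.3, 1.2),
        "complex_length": (25.1, 0.4), "complex_width": (13.0, 0.3),
        "junction_area": (46.4, 1.0), "guard_cell_width": (5.9, 0.1),
        "guard_cell_arc_length": (22.2, 1.3),
    },
    ("open", "Col-0"): {
        "pore_width": (3.9, 0.2), "pore_length": (13.6, 0.5),
        "aspect_ratio": (0.30, 0.02), "pore_area": (42.3, 2.6),
        "complex_length": (25.4, 0.5), "complex_width": (16.9, 0.3),
        "junction_area": (44.1, 0.9), "guard_cell_width": (6.5, 0.1),
        "guard_cell_arc_length": (24.0, 0.3),
    },
    ("open", "cesa3je5"): {
        "pore_width": (4.7, 0.4), "pore_length": (10.0, 0.9),
        "aspect_ratio": (0.48, 0.03), "pore_area": (41.8, 4.8),
        "complex_length": (22.7, 0.5), "complex_width": (18.1, 0.3),
        "junction_area": (48.0, 0.9), "guard_cell_width": (6.7, 0.1),
        "guard_cell_arc_length": (23.3, 0.5),
    },
    ("open", "xxt1xxt2"): {
        "pore_width": (2.3, 0.2), "pore_length": (8.5, 0.6),
        "aspect_ratio": (0.29, 0.02), "pore_area": (17.5, 2.0),
        "complex_length": (21.8, 0.5), "complex_width": (15.2, 0.2),
        "junction_area": (45.2, 1.0), "guard_cell_width": (6.5, 0.1),
        "guard_cell_arc_length": (20.0, 0.3),
    },
    ("open", "PGX1OE"): {
        "pore_width": (4.5, 0.2), "pore_length": (12.0, 0.5),
        "aspect_ratio": (0.38, 0.02), "pore_area": (45.6, 3.7),
        "complex_length": (24.3, 0.5), "complex_width": (18.0, 0.4),
        "junction_area": (45.6, 1.0), "guard_cell_width": (6.8, 0.1),
        "guard_cell_arc_length": (24.4, 0.5),
    },
}

#: Reference sample size behind the published mean ± SE rows (the study
#: reports n > 15 complexes per genotype); per-row SD = SE·√N_REF.
N_REF = 15

GEOMETRY_COLUMNS = [
    "pore_width", "pore_length", "aspect_ratio", "pore_area",
    "complex_length", "complex_width", "junction_area",
    "guard_cell_width", "guard_cell_arc_length",
]


@dataclass
class ParametricComplex:
    """Nominal dimensions (μm) of a simplified guard-cell pair: an elliptical
    pore surrounded by an elliptical torus of elliptical cross-section."""

    pore_width: float
    pore_length: float
    complex_length: float
    complex_width: float
    guard_cell_width: float
    wall_thickness: float = 0.5

    def __post_init__(self):
        vals = asdict(self)
        for k, v in vals.items():
            if v <= 0:
                raise ValueError(f"{k} must be > 0, got {v}")
        if self.pore_width > self.pore_length:
            raise ValueError("pore_width must be ≤ pore_length")
        if self.pore_width >= self.complex_width:
            raise ValueError("degenerate dimensions: pore_width ≥ complex_width")
        if self.pore_length >= self.complex_length:
            raise ValueError("degenerate dimensions: pore_length ≥ complex_length")

    @classmethod
    def from_published(cls, genotype: str = "Col-0", state: str = "closed",
                    wall_thickness: float = 0.5) -> "ParametricComplex":
        row = PUBLISHED_GEOMETRY[(state, genotype)]
        return cls(
            pore_width=row["pore_width"][0],
            pore_length=row["pore_length"][0],
            complex_length=row["complex_length"][0],
            complex_width=row["complex_width"][0],
            guard_cell_width=row["guard_cell_width"][0],
            wall_thickness=wall_thickness,
        )

    # derived mid-surface ellipses --------------------------------------
    @property
    def pore_semi(self):
        return self.pore_length / 2.0, self.pore_width / 2.0

    @property
    def outer_semi(self):
        return self.complex_length / 2.0, self.complex_width / 2.0


@dataclass
class GroundTruth:
    """Generation provenance attached to a synthetic stack."""

    geometry: dict
    rng_seed: int = 0
    noise_sd: float = 0.0
    psf_sigma: float = 0.0
    outlier_slices: tuple = ()

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# Parametric torus mesh
# ---------------------------------------------------------------------------


def _ring_grid(params: ParametricComplex, n_rings: int, n_per_ring: int):
    """Vertex grid x(θ, ψ) of the elliptical-torus mid-surface.

    θ parameterizes the sweep around the pore (θ = 0, π at the junction
    poles; cell 1 is θ ∈ (0, π), cell 2 the rest); ψ the tube cross-section
    (ψ = 0 dorsal/outer equator, ψ = π the pore rim).
    """
    ap, bp = params.pore_semi
    ao, bo = params.outer_semi
    v = params.guard_cell_width / 2.0
    theta = 2 * np.pi * np.arange(n_rings) / n_rings
    psi = 2 * np.pi * np.arange(n_per_ring) / n_per_ring
    e_in = np.stack([ap * np.cos(theta), bp * np.sin(theta)], axis=1)
    e_out = np.stack([ao * np.cos(theta), bo * np.sin(theta)], axis=1)
    c = 0.5 * (e_in + e_out)
    d = 0.5 * (e_out - e_in)
    u = np.linalg.norm(d, axis=1)
    m = d / u[:, None]
    grid = np.empty((n_rings, n_per_ring, 3))
    grid[..., 0] = c[:, None, 0] + u[:, None] * np.cos(psi)[None, :] * m[:, None, 0]
    grid[..., 1] = c[:, None, 1] + u[:, None] * np.cos(psi)[None, :] * m[:, None, 1]
    grid[..., 2] = v * np.sin(psi)[None, :]
    return grid, theta, psi


def generate_torus_complex(
    params: ParametricComplex,
    resolution: tuple = (48, 32),
    thickness_table: ThicknessTable | None = None,
) -> ShellMesh:
    """Build the mid-surface shell mesh of a simplified guard-cell pair.

    The pair is one closed elliptical torus: the pore-side rim traces the
    pore ellipse and the outer rim the complex ellipse, with an elliptical
    tube cross-section (out-of-plane semi-axis = guard_cell_width/2). The
    two guard cells are the θ ∈ (0, π) and θ ∈ (π, 2π) halves, meeting at
    the junction poles. Material frames: e1 longitudinal (along the sweep),
    e2 hoop, e3 outward normal. Thickness defaults to the uniform nominal
    wall thickness.

    resolution = (n_rings around the pore, n_points per cross-section);
    multiples of 4 sample the extreme dimensions exactly.
    """
    n_rings, n_per_ring = resolution
    if n_rings < 8 or n_per_ring < 8:
        raise ValueError(f"resolution must be ≥ 8×8, got {resolution}")
    grid, theta, psi = _ring_grid(params, n_rings, n_per_ring)
    mesh = triangulate_ring_grid(grid, closed=True)
    idx = np.asarray(mesh.rings[1])
    half = n_rings // 2

    j_pore = n_per_ring // 2
    mesh.node_sets["pore_rim"] = idx[:, j_pore].copy()
    mesh.node_sets["dorsal"] = idx[:, 0].copy()
    mesh.node_sets["ventral"] = idx[:, j_pore].copy()
    quarter = n_per_ring // 4
    mesh.node_sets["periclinal"] = np.concatenate(
        [idx[:, quarter], idx[:, (3 * n_per_ring) // 4]]
    )
    mesh.node_sets["junction"] = np.concatenate([idx[0], idx[half]])

    # frames from the full closed sweep grid (e1 along the sweep, e2 hoop,
    # e3 outward), then split the rings into the two guard cells at the
    # junction poles
    assign_material_frames(mesh)
    mesh.rings = {1: idx[: half + 1], 2: np.vstack([idx[half:], idx[:1]])}
    if thickness_table is None:
        thickness_table = ThicknessTable.uniform(params.wall_thickness)
    assign_regions_and_thickness(mesh, thickness_table)
    return mesh


def measure_mesh_dimensions(mesh: ShellMesh) -> dict:
    """Nominal dimensions read back from a parametric mesh (μm)."""
    rim = mesh.nodes[mesh.node_sets["pore_rim"]]
    out = {}
    out["pore_length"] = rim[:, 0].max() - rim[:, 0].min()
    out["pore_width"] = rim[:, 1].max() - rim[:, 1].min()
    out["complex_length"] = mesh.nodes[:, 0].max() - mesh.nodes[:, 0].min()
    out["complex_width"] = mesh.nodes[:, 1].max() - mesh.nodes[:, 1].min()
    out["guard_cell_width"] = mesh.nodes[:, 2].max() - mesh.nodes[:, 2].min()
    return out


def analytic_torus_area(params: ParametricComplex, n_quad: int = 2048) -> float:
    """Surface area of the analytic elliptical torus by numeric quadrature."""
    grid, _, _ = _ring_grid(params, n_quad, n_quad // 4)
    # dense quadrature via cross products of parametric partials
    g = np.concatenate([grid, grid[:1]], axis=0)
    g = np.concatenate([g, g[:, :1]], axis=1)
    d_theta = np.diff(g[:, :-1], axis=0)
    d_psi = np.diff(g[:-1], axis=1)
    return float(np.linalg.norm(np.cross(d_theta, d_psi), axis=2).sum())


# ---------------------------------------------------------------------------
# Synthetic landmark rings
# ---------------------------------------------------------------------------


def generate_landmarks(
    params: ParametricComplex,
    n_rings_per_cell: int = 12,
    n_points_per_ring: int = 12,
    jitter: float = 0.0,
    seed: int = 0,
) -> LandmarkSet:
    """Landmark rings along each guard-cell tube, as a manual tracer would
    place them: cross-section loops at stations along the cell, optionally
    jittered (μm SD) to emulate tracing error."""
    rng = np.random.default_rng(seed)
    total = 2 * n_rings_per_cell
    grid, theta, psi = _ring_grid(params, total, n_points_per_ring)
    half = total // 2
    rings = {
        1: [grid[i] + rng.normal(0, jitter, grid[i].shape) for i in range(half + 1)],
        2: [grid[i % total] + rng.normal(0, jitter, grid[i % total].shape)
            for i in range(half, total + 1)],
    }
    flags = {
        1: [i in (0, half) for i in range(half + 1)],
        2: [i in (half, total) for i in range(half, total + 1)],
    }
    return LandmarkSet(rings=rings, junction_flags=flags)


# ---------------------------------------------------------------------------
# Synthetic image stacks
# ---------------------------------------------------------------------------


def _face_surface_samples(params: ParametricComplex, which: str,
                          spacing: float = 0.1):
    """Dense sampling (points + outward normals) of a wall face surface.

    ``which`` = "outer" samples the stained-wall outer faces (in-plane span
    from the pore ellipse to the complex ellipse, full nominal cell height);
    "lumen" the inner faces one wall thickness inside. Both are closed
    tori, so a nearest-sample normal test classifies inside/outside exactly
    up to sampling error.
    """
    t = params.wall_thickness
    ap, bp = params.pore_semi
    ao, bo = params.outer_semi
    n_th = max(64, int(np.ceil(2 * np.pi * max(ao, bo) / spacing)))
    n_ps = max(32, int(np.ceil(np.pi * max(bo - bp, params.guard_cell_width)
                               / spacing)))
    theta = 2 * np.pi * np.arange(n_th) / n_th
    psi = 2 * np.pi * np.arange(n_ps) / n_ps
    e_in = np.stack([ap * np.cos(theta), bp * np.sin(theta)], axis=1)
    e_out = np.stack([ao * np.cos(theta), bo * np.sin(theta)], axis=1)
    c = 0.5 * (e_in + e_out)
    dvec = 0.5 * (e_out - e_in)
    gap = np.linalg.norm(dvec, axis=1)
    m_hat = dvec / gap[:, None]
    if which == "outer":
        u = gap
        v = params.guard_cell_width / 2.0
    elif which == "lumen":
        u = np.maximum(gap - t, 0.02)
        v = max(params.guard_cell_width / 2.0 - t, 0.02)
    else:
        raise ValueError(which)
    pts = np.empty((n_th, n_ps, 3))
    cpsi, spsi = np.cos(psi), np.sin(psi)
    pts[..., 0] = c[:, None, 0] + u[:, None] * cpsi[None, :] * m_hat[:, None, 0]
    pts[..., 1] = c[:, None, 1] + u[:, None] * cpsi[None, :] * m_hat[:, None, 1]
    pts[..., 2] = v * spsi[None, :]
    # outward normals from the parametric partials (numeric, periodic)
    d_th = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    d_ps = np.roll(pts, -1, axis=1) - np.roll(pts, 1, axis=1)
    nrm = np.cross(d_th.reshape(-1, 3), d_ps.reshape(-1, 3))
    ln = np.linalg.norm(nrm, axis=1, keepdims=True)
    ln[ln < 1e-15] = 1.0
    nrm /= ln
    flat = pts.reshape(-1, 3)
    # orient outward: positive dot with the cross-section radial direction
    radial = flat - np.repeat(
        np.column_stack([c, np.zeros(n_th)]), n_ps, axis=0)
    flip = np.einsum("ij,ij->i", nrm, radial) < 0
    nrm[flip] *= -1.0
    return flat, nrm


def generate_stack(
    params: ParametricComplex,
    truth: GroundTruth | None = None,
    pixel_size: float = PIXEL_SIZE_UM,
    z_step: float = Z_STEP_UM,
    margin: float = 2.0,
    shape: tuple | None = None,
    sample_spacing: float = 0.1,
):
    """Render a PI-stained-like stack of one stomatal complex.

    Walls are rendered as a bright shell ([0, 1] intensity before
    degradation): voxels within half a wall thickness of the tube
    mid-surface (plus junction end walls where the two cells contact). The
    band straddles the mid-surface so the visible aperture equals the
    nominal pore dimensions and the visible outer extent the nominal
    complex dimensions. Gaussian PSF blur (``truth.psf_sigma`` um) is
    applied before additive Gaussian noise (``truth.noise_sd``); listed
    ``outlier_slices`` are corrupted afterwards to exercise robust fitting.

    Returns an :class:`~stomech.morphometry.ImageStack` with the ground
    truth attached.
    """
    from scipy.spatial import cKDTree

    from .morphometry import ImageStack

    if pixel_size <= 0 or z_step <= 0:
        raise ValueError("voxel calibration must be positive")
    t = params.wall_thickness
    ao, bo = params.outer_semi
    v_mid = params.guard_cell_width / 2.0 - t / 2.0
    if v_mid <= 0:
        raise ValueError("guard_cell_width too small for wall thickness")

    half_x = ao + margin
    half_y = bo + margin
    half_z = v_mid + t / 2.0 + margin / 2.0
    if shape is None:
        nx = int(np.ceil(2 * half_x / pixel_size))
        ny = int(np.ceil(2 * half_y / pixel_size))
        nz = int(np.ceil(2 * half_z / z_step))
        shape = (nz, ny, nx)
    nz, ny, nx = shape
    if nx * pixel_size < 2 * ao or ny * pixel_size < 2 * bo or nz * z_step < 2 * v_mid:
        raise ValueError(f"stack shape {shape} too small to contain the complex")

    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_size
    z = (np.arange(nz) - (nz - 1) / 2.0) * z_step

    p_out, n_out = _face_surface_samples(params, "outer", sample_spacing)
    p_lum, n_lum = _face_surface_samples(params, "lumen", sample_spacing)
    tree_out = cKDTree(p_out)
    tree_lum = cKDTree(p_lum)
    # junction end walls fill the cross-section in thin wedges at the poles
    ap, _ = params.pore_semi
    r_pole = 0.5 * (ap + ao)
    wedge = (t / 2.0) / r_pole

    vol = np.empty((nz, ny, nx), dtype=np.float32)
    X, Y = np.meshgrid(x, y)
    flat_xy = np.stack([X.ravel(), Y.ravel()], axis=1)
    theta_xy = np.arctan2(Y, X).ravel()
    near_pole = np.minimum(np.abs(theta_xy), np.pi - np.abs(theta_xy)) <= wedge
    for zi, zz in enumerate(z):
        pts = np.column_stack([flat_xy, np.full(len(flat_xy), zz)])
        _, i_out = tree_out.query(pts, workers=-1)
        inside_out = np.einsum(
            "ij,ij->i", pts - p_out[i_out], n_out[i_out]) < 0.0
        _, i_lum = tree_lum.query(pts, workers=-1)
        inside_lum = np.einsum(
            "ij,ij->i", pts - p_lum[i_lum], n_lum[i_lum]) < 0.0
        wall = (inside_out & ~inside_lum) | (inside_out & near_pole)
        vol[zi] = wall.reshape(ny, nx).astype(np.float32)

    rng = np.random.default_rng(truth.rng_seed)
    if truth.psf_sigma > 0:
        vol = gaussian_filter(
            vol, sigma=(truth.psf_sigma / z_step,
                        truth.psf_sigma / pixel_size,
                        truth.psf_sigma / pixel_size)
        )
    if truth.noise_sd > 0:
        vol = vol + rng.normal(0, truth.noise_sd, vol.shape).astype(np.float32)
    for zi in truth.outlier_slices:
        vol[int(zi)] = np.clip(
            vol[int(zi)] * 0.2 + rng.normal(0.5, 0.3, vol[int(zi)].shape), 0, None
        ).astype(np.float32)

    truth.geometry = visible_geometry(params)
    # the pore area a rasterized image can show: pixel centres inside the
    # aperture ellipse at this grid (thin closed pores quantize visibly)
    ap_, bp_ = params.pore_semi
    Xc, Yc = np.meshgrid(x, y)
    truth.geometry["pore_area"] = float(
        np.sum((Xc / ap_) ** 2 + (Yc / bp_) ** 2 < 1.0) * pixel_size**2)
    stack = ImageStack(
        voxels=np.asarray(vol, dtype=np.float32),
        pixel_area_xy=pixel_size**2,
        z_step=z_step,
    )
    stack.truth = truth
    return stack


def visible_geometry(params: ParametricComplex) -> dict:
    """Ground-truth geometry as it appears in a rendered stack (μm, μm²).

    Pore dimensions are the aperture between lumen-side wall faces (the
    nominal pore ellipse); complex dimensions are outer wall faces (nominal
    complex ellipse); the guard-cell width is the peak-to-peak distance
    between the ventral and dorsal wall band centres; the arc length is the
    length of the in-plane cell centerline between the junction poles.
    """
    ap, bp = params.pore_semi
    t = params.wall_thickness
    theta = np.linspace(0, np.pi, 4096)
    e_in = np.stack([ap * np.cos(theta), bp * np.sin(theta)], axis=1)
    ao, bo = params.outer_semi
    e_out = np.stack([ao * np.cos(theta), bo * np.sin(theta)], axis=1)
    c = 0.5 * (e_in + e_out)
    arc = float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())
    gap = np.linalg.norm(e_out - e_in, axis=1)
    mid_gap = float(gap[len(gap) // 2])
    return {
        "pore_width": params.pore_width,
        "pore_length": params.pore_length,
        "aspect_ratio": params.pore_width / params.pore_length,
        "pore_area": float(np.pi * ap * bp),
        "complex_length": params.complex_length,
        "complex_width": params.complex_width,
        "guard_cell_width": mid_gap - t,  # wall band centre to centre
        "guard_cell_arc_length": arc,
        "junction_angles_deg": (0.0, 180.0),
    }


def write_stack(stack, path, truth_path=None) -> None:
    """Write a stack as multi-page TIFF with resolution metadata; optionally
    the ground truth as a JSON sidecar."""
    px = float(np.sqrt(stack.pixel_area_xy))
    tifffile.imwrite(
        path,
        stack.voxels,
        resolution=(1.0 / px, 1.0 / px),
        metadata={"spacing": stack.z_step, "unit": "um", "axes": "ZYX"},
    )
    if truth_path is not None and getattr(stack, "truth", None) is not None:
        stack.truth.to_json(truth_path)


def read_stack(path):
    from .morphometry import ImageStack

    with tifffile.TiffFile(path) as tif:
        vol = tif.asarray()
        px = PIXEL_SIZE_UM
        z = Z_STEP_UM
        try:
            res = tif.pages[0].tags["XResolution"].value
            px = res[1] / res[0]
        except (KeyError, ZeroDivisionError):
            pass
        meta = tif.imagej_metadata or {}
        z = float(meta.get("spacing", z))
    return ImageStack(voxels=vol, pixel_area_xy=px * px, z_step=z)


# ---------------------------------------------------------------------------
# Geometry tables
# ---------------------------------------------------------------------------


def generate_geometry_table(
    genotype_spec: dict | None = None,
    n: int = 20,
    seed: int = 0,
    n_ref: int = N_REF,
) -> pd.DataFrame:
    """Sample per-complex geometry rows around published means/SEs.

    ``genotype_spec`` maps (state, genotype) -> {column: (mean, SE)}; the
    default is the published wild-type/mutant table. Each row is drawn from
    N(mean, SE·√n_ref) — the SE refers to a sample of about ``n_ref``
    complexes — truncated at zero (negative draws are resampled and the row
    flagged). The sample mean of each column lies within 3 SE of the
    specified mean with near certainty.
    """
    if genotype_spec is None:
        genotype_spec = PUBLISHED_GEOMETRY
    if n < 2:
        raise ValueError("need n ≥ 2 rows per genotype/state")
    rng = np.random.default_rng(seed)
    frames = []
    for (state, genotype), cols in genotype_spec.items():
        data = {"state": [state] * n, "genotype": [genotype] * n}
        truncated = np.zeros(n, dtype=bool)
        for col, (mean, se) in cols.items():
            if se < 0:
                raise ValueError(f"negative SE for {col}")
            sd = se * np.sqrt(n_ref)
            draws = rng.normal(mean, sd, n)
            bad = draws <= 0
            tries = 0
            while bad.any() and tries < 100:
                draws[bad] = rng.normal(mean, sd, bad.sum())
                truncated |= bad
                bad = draws <= 0
                tries += 1
            draws[bad] = mean  # pathological spec; clamp
            data[col] = draws
        data["resampled"] = truncated
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
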