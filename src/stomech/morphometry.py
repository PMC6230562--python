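"""Semi-automated 3D morphometry of stomatal complexes.

Measures the standard geometry set of a stomatal complex from a confocal-like
z-stack: per-slice active-contour segmentation of the pore, a robust
(Cauchy-loss) quartic regression of the pore-area profile across depth to
locate the minimum pore section, connected-component axes for pore and
complex dimensions, and a radial-intensity medial axis per guard cell whose
arc length gives the tangential cell length.

Pixel/μm conversion uses the imaging calibration carried by the stack
(default 0.0409 μm² per XY pixel, 0.2 μm z-step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks, savgol_filter
from skimage import measure as skmeasure
from skimage.filters import gaussian as sk_gaussian
from skimage.segmentation import (
    disk_level_set,
    inverse_gaussian_gradient,
    morphological_geodesic_active_contour,
)

from .units import PIXEL_AREA_UM2, Z_STEP_UM


class MeasurementError(RuntimeError):
    """Raised when a morphometry stage fails; carries the stage identity."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ImageStack:
    """3D intensity grid (z, y, x) with physical voxel calibration."""

    voxels: np.ndarray
    pixel_area_xy: float = PIXEL_AREA_UM2
    z_step: float = Z_STEP_UM

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.pixel_area_xy <= 0 or self.z_step <= 0:
            raise ValueError("voxel calibration must be positive")
        nz, ny, nx = self.voxels.shape
        if nx < 16 or ny < 16 or nz < 4:
            raise ValueError(f"stack too small: {self.voxels.shape}, need ≥16×16×4")

    @property
    def pixel_size(self) -> float:
        return math.sqrt(self.pixel_area_xy)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class SliceSegmentation:
    slice_index: int
    mask: np.ndarray
    contour: np.ndarray  # (k, 2) closed polyline in (row, col) pixel coords
    converged: bool = True

    def __post_init__(self):
        if int(self.mask.sum()) == 0:
            raise ValueError("empty segmentation mask")

    @property
    def area_px(self) -> float:
        return float(self.mask.sum())


@dataclass
class ActiveContourParams:
    """Knobs of the morphological geodesic active contour.

    ``sigma`` smooths the slice before the edge map (px); ``alpha`` scales
    the inverse-gradient edge weight; ``balloon`` is the expansion force;
    ``smoothing`` the per-iteration curve regularization; ``max_iterations``
    the iteration budget; ``init_radius`` the seed-disk radius (px).
    """

    sigma: float = 1.0
    alpha: float = 400.0
    balloon: float = 1.0
    smoothing: int = 0
    max_iterations: int = 500
    init_radius: float = 2.0
    threshold: float = 0.3
    #: intensity barrier: fraction of the slice intensity range above which
    #: pixels count as stained wall (the pore and lumen are dark); high
    #: enough that one-pixel dark corridors at the pore tips stay passable
    wall_cutoff: float = 0.45
    #: smoothing used only for the wall barrier (px); kept small so thin
    #: dark corridors are not washed out
    barrier_sigma: float = 0.5


@dataclass
class PoreProfile:
    areas_px: np.ndarray  # per-slice pore area, NaN where unusable
    fit_coefficients: np.ndarray = None
    min_slice: int = None
    min_area_px: float = None

    @property
    def usable(self) -> np.ndarray:
        return ~np.isnan(self.areas_px)


@dataclass
class StomatalGeometry:
    """The Figure-style measurement set of one stomatal complex (μm, μm²).

    ``junction_area`` is optional (measured manually in practice, not
    automated here). Pore fields may be None for non-stomatal geometries.
    """

    pore_width: float = None
    pore_length: float = None
    aspect_ratio: float = None
    pore_area: float = None
    complex_length: float = None
    complex_width: float = None
    guard_cell_width: float = None
    guard_cell_arc_length: float = None
    junction_area: float = None

    def __post_init__(self):
        if self.pore_width is not None and self.pore_length:
            ar = self.pore_width / self.pore_length
            if self.aspect_ratio is None:
                self.aspect_ratio = ar
            elif abs(self.aspect_ratio - ar) > 0.02 + 1e-9:
                raise ValueError(
                    f"inconsistent aspect ratio {self.aspect_ratio} vs "
                    f"width/length {ar:.3f}")

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("pore_width", "pore_length", "aspect_ratio", "pore_area",
                      "complex_length", "complex_width", "guard_cell_width",
                      "guard_cell_arc_length", "junction_area")
        }


@dataclass
class MedialAxis:
    """Ordered midline of one guard cell (μm) and its arc length."""

    points: np.ndarray
    arc_length: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) >= 2:
            ln = float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())
            if not math.isclose(ln, self.arc_length, rel_tol=1e-6, abs_tol=1e-9):
                raise ValueError("arc_length does not match the polyline length")


# ---------------------------------------------------------------------------
# Active-contour segmentation
# ---------------------------------------------------------------------------


def segment_active_contour(
    slice_img: np.ndarray,
    seed_points: np.ndarray,
    params: ActiveContourParams | None = None,
) -> SliceSegmentation:
    """Segment one region of a slice with a balloon-driven geodesic active
    contour.

    A small level-set disk is initialized at the seed centroid and expands
    against the edge map (inverse Gaussian gradient) of the slice until it
    locks onto intensity edges. Non-convergence within the iteration budget
    is flagged on the result; a featureless (edge-free) slice raises.
    """
    if params is None:
        params = ActiveContourParams()
    img = np.asarray(slice_img, dtype=float)
    seeds = np.atleast_2d(np.asarray(seed_points, dtype=float))
    if seeds.shape[0] < 1:
        raise ValueError("need at least one seed point")
    rng_span = img.max() - img.min()
    grad = np.hypot(*np.gradient(sk_gaussian(img, params.sigma, preserve_range=True)))
    if rng_span < 1e-12 or grad.max() < 1e-9:
        raise MeasurementError("active_contour", "featureless slice (no edges)")

    gimage = inverse_gaussian_gradient(img, alpha=params.alpha, sigma=params.sigma)
    if params.wall_cutoff is not None:
        # walls stop the curve outright; away from walls the balloon must
        # stay live even where the blurred edge zone depresses the speed
        smooth = sk_gaussian(img, params.barrier_sigma, preserve_range=True)
        barrier = smooth > smooth.min() + params.wall_cutoff * (
            smooth.max() - smooth.min())
        gimage = np.where(barrier, 0.0,
                          np.maximum(gimage, params.threshold * 1.05))
    center = seeds.mean(axis=0)  # (row, col)
    init = disk_level_set(img.shape, center=tuple(center), radius=params.init_radius)

    snapshots = []

    def record(ls):
        if len(snapshots) == 0 or not np.array_equal(snapshots[-1], ls):
            snapshots.append(ls.copy())

    mask = morphological_geodesic_active_contour(
        gimage,
        num_iter=params.max_iterations,
        init_level_set=init,
        smoothing=params.smoothing,
        balloon=params.balloon,
        threshold=params.threshold,
        iter_callback=record,
    ).astype(bool)
    converged = len(snapshots) < params.max_iterations + 1
    if params.wall_cutoff is not None:
        # the attachment term parks the curve on the bright wall; the
        # segmented region is the enclosed non-wall interior
        mask &= ~barrier
        labels, n = ndimage.label(mask)
        seed_px = (int(round(center[0])), int(round(center[1])))
        lab = labels[seed_px]
        if lab == 0 and n >= 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       np.arange(1, n + 1))
            lab = int(np.argmax(sizes)) + 1
        mask = labels == lab
    if mask.sum() == 0:
        raise MeasurementError("active_contour", "contour collapsed to nothing")
    contours = skmeasure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise MeasurementError("active_contour", "no contour found")
    contour = max(contours, key=len)
    return SliceSegmentation(
        slice_index=-1, mask=mask, contour=contour, converged=converged)


# ---------------------------------------------------------------------------
# Pore-area profile and robust minimum
# ---------------------------------------------------------------------------


def pore_area_profile(
    stack: ImageStack,
    seeds_per_slice=None,
    params: ActiveContourParams | None = None,
) -> PoreProfile:
    """Per-slice pore area (pixels) via active-contour segmentation.

    Slices where segmentation fails, runs out of the frame, or floods more
    than a third of the image are marked missing (NaN), not zero. The pore
    seed defaults to the stack center.
    """
    nz, ny, nx = stack.voxels.shape
    if seeds_per_slice is None:
        seeds_per_slice = [np.array([[ny / 2.0, nx / 2.0]])] * nz
    areas = np.full(nz, np.nan)
    smooth_stack = ndimage.gaussian_filter(
        np.asarray(stack.voxels, dtype=float), (0, 1.0, 1.0))
    bright_level = stack.voxels.min() + 0.5 * np.ptp(smooth_stack)
    for zi in range(nz):
        # slices outside the stained complex carry no wall signal
        if np.mean(smooth_stack[zi] > bright_level) < 0.005:
            continue
        try:
            seg = segment_active_contour(stack.voxels[zi], seeds_per_slice[zi], params)
        except (MeasurementError, ValueError):
            continue
        mask = seg.mask
        border = (mask[0].any() or mask[-1].any()
                  or mask[:, 0].any() or mask[:, -1].any())
        if border or mask.sum() > 0.33 * mask.size:
            continue
        areas[zi] = mask.sum()
    usable = int(np.sum(~np.isnan(areas)))
    if usable < 5:
        raise MeasurementError(
            "pore_profile", f"only {usable} usable slices (need ≥5)")
    return PoreProfile(areas_px=areas)


def _cauchy_irls_polyfit(z: np.ndarray, y: np.ndarray, degree: int = 4,
                         n_iter: int = 60, tol: float = 1e-10):
    """Quartic fit by maximum likelihood under Cauchy-distributed residuals,
    solved as iteratively reweighted least squares (weights 1/(1+(r/c)²),
    scale c = median absolute residual)."""
    z0, zs = z.mean(), max(z.std(), 1e-9)
    zn = (z - z0) / zs
    V = np.vander(zn, degree + 1)
    # seed the weights from a fit to the median-filtered profile so an
    # isolated outlier cannot anchor the first least-squares pass
    y_med = ndimage.median_filter(y, size=3, mode="nearest")
    coef0, *_ = np.linalg.lstsq(V, y_med, rcond=None)
    r0 = y - V @ coef0
    c0 = max(np.median(np.abs(r0)), 1e-9 * max(np.abs(y).max(), 1.0))
    w = 1.0 / np.sqrt(1.0 + (r0 / c0) ** 2)
    coef = None
    for _ in range(n_iter):
        W = w[:, None]
        coef_new, *_ = np.linalg.lstsq(V * W, y * w, rcond=None)
        r = y - V @ coef_new
        c = np.median(np.abs(r))
        c = max(c, 1e-9 * max(np.abs(y).max(), 1.0))
        w_new = 1.0 / np.sqrt(1.0 + (r / c) ** 2)
        if coef is not None and np.max(np.abs(coef_new - coef)) < tol * (
                1 + np.max(np.abs(coef))):
            coef = coef_new
            break
        coef, w = coef_new, w_new
    return coef, z0, zs


def robust_min_area(
    profile, pixel_area: float = PIXEL_AREA_UM2
) -> tuple[int, float, float]:
    """Minimum pore area from the robust quartic regression of the profile.

    Fits a fourth-order polynomial assuming Cauchy residual variance (IRLS),
    takes the minimum of the regression curve inside the measured z-range,
    and converts pixels to μm² with the physical pixel area. If the fitted
    curve is monotone over the range, the endpoint minimum is returned and
    flagged via the returned profile's ``fit_coefficients`` (a warning is
    emitted).

    Accepts a PoreProfile or a plain per-slice area array (NaN = missing).
    Returns (min_slice, min_area_px, min_area_um2).
    """
    if isinstance(profile, PoreProfile):
        areas = profile.areas_px
        out = profile
    else:
        areas = np.asarray(profile, dtype=float)
        out = PoreProfile(areas_px=areas)
    ok = ~np.isnan(areas)
    if ok.sum() < 5:
        raise MeasurementError("robust_min", "need ≥5 non-missing points")
    z = np.where(ok)[0].astype(float)
    y = areas[ok]
    if np.ptp(y) < 1e-12:  # constant profile
        out.min_slice, out.min_area_px = int(z[0]), float(y[0])
        out.fit_coefficients = np.array([0, 0, 0, 0, y[0]])
        return out.min_slice, out.min_area_px, out.min_area_px * pixel_area
    # two-stage fit: a robust full-range pass locates the basin, then the
    # quartic is refit inside a window around it so the steep wings of deep
    # V-shaped profiles cannot dominate the polynomial
    coef, z0, zs = _cauchy_irls_polyfit(z, y)
    grid = np.linspace(z.min(), z.max(), 2001)
    center = grid[int(np.argmin(np.polyval(coef, (grid - z0) / zs)))]
    window = max(4.0, 0.2 * (z.max() - z.min()))
    keep = np.abs(z - center) <= window
    if 5 <= keep.sum() < len(z):
        z, y = z[keep], y[keep]
        coef, z0, zs = _cauchy_irls_polyfit(z, y)
    out.fit_coefficients = coef
    zn = np.linspace((z.min() - z0) / zs, (z.max() - z0) / zs, 2001)
    vals = np.polyval(coef, zn)
    i_min = int(np.argmin(vals))
    min_zn = zn[i_min]
    min_val = float(vals[i_min])
    if i_min in (0, len(zn) - 1):
        import warnings

        warnings.warn("fitted pore-area curve is monotone over the z-range; "
                      "returning the endpoint minimum", stacklevel=2)
    min_z = min_zn * zs + z0
    # nearest actually-measured slice
    out.min_slice = int(z[np.argmin(np.abs(z - min_z))])
    out.min_area_px = min_val
    return out.min_slice, out.min_area_px, out.min_area_px * pixel_area


# ---------------------------------------------------------------------------
# Connected-component axes and complex dimensions
# ---------------------------------------------------------------------------


def component_axes(mask: np.ndarray, pixel_size: float = None) -> tuple[float, float]:
    """Major/minor axis lengths (μm) of the largest connected component,
    from its second central moments (ellipse-equivalent axes)."""
    if pixel_size is None:
        pixel_size = math.sqrt(PIXEL_AREA_UM2)
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise MeasurementError("component_axes", "empty mask")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = labels == keep
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    return (props.axis_major_length * pixel_size,
            props.axis_minor_length * pixel_size)


def _segment_complex(slice_img: np.ndarray, params: ActiveContourParams | None = None):
    """Whole-complex segmentation.

    A bright-wall mask (half-range threshold on the lightly smoothed slice)
    is hole-filled to a first estimate of the complex, which then seeds a
    short geodesic active-contour relaxation that locks the boundary onto
    the outer wall edge.
    """
    if params is None:
        params = ActiveContourParams()
    img = np.asarray(slice_img, dtype=float)
    smooth = sk_gaussian(img, max(params.sigma, 0.5), preserve_range=True)
    cutoff = smooth.min() + params.wall_cutoff * (smooth.max() - smooth.min())
    bright = smooth > cutoff
    first = ndimage.binary_fill_holes(bright)
    labels, n = ndimage.label(first)
    if n == 0:
        raise MeasurementError("complex_dims", "no bright walls found")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   np.arange(1, n + 1))
        first = labels == (int(np.argmax(sizes)) + 1)
    gimage = inverse_gaussian_gradient(img, alpha=params.alpha, sigma=params.sigma)
    mask = morphological_geodesic_active_contour(
        gimage, num_iter=30, init_level_set=first.astype(np.int8),
        smoothing=1, balloon=0, threshold=params.threshold,
    ).astype(bool)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    if mask.sum() == 0:
        raise MeasurementError("complex_dims", "complex segmentation collapsed")
    return mask


def _contour_contrast(slice_img: np.ndarray, mask: np.ndarray) -> float:
    """Mean gradient magnitude along the mask boundary (contrast score)."""
    img = sk_gaussian(np.asarray(slice_img, dtype=float), 1.0, preserve_range=True)
    grad = np.hypot(*np.gradient(img))
    boundary = mask ^ ndimage.binary_erosion(mask)
    if boundary.sum() == 0:
        return 0.0
    return float(grad[boundary].mean())


def complex_dimensions(
    stack: ImageStack,
    min_slice: int,
    params: ActiveContourParams | None = None,
    neighborhood: int = 4,
) -> tuple[float, float]:
    """Stomatal complex length/width (μm) near the minimum-pore slice.

    Segments the whole complex on the slice within ±``neighborhood`` of
    ``min_slice`` that shows the best wall contrast (maximal mean gradient
    along the segmented contour; ties broken toward the lowest index), then
    reads the component's major/minor axes.
    """
    nz = stack.n_slices
    if not 0 <= min_slice < nz:
        raise MeasurementError("complex_dims", f"min_slice {min_slice} out of range")
    candidates = [z for z in range(min_slice - neighborhood,
                                   min_slice + neighborhood + 1) if 0 <= z < nz]
    best = None
    for z in candidates:
        try:
            mask = _segment_complex(stack.voxels[z], params)
        except MeasurementError:
            continue
        score = _contour_contrast(stack.voxels[z], mask)
        if best is None or score > best[0] + 1e-12:
            best = (score, z, mask)
    if best is None:
        raise MeasurementError(
            "complex_dims", "no segmentable slice in the four-slice neighborhood")
    _, _, mask = best
    major, minor = component_axes(mask, stack.pixel_size)
    return major, minor


# ---------------------------------------------------------------------------
# Radial-profile medial axis
# ---------------------------------------------------------------------------


def _radial_profile(img, center, angle_deg, r_max, step=0.25):
    r = np.arange(0.0, r_max, step)
    yy = center[0] + r * np.sin(np.radians(angle_deg))
    xx = center[1] + r * np.cos(np.radians(angle_deg))
    vals = ndimage.map_coordinates(img, np.vstack([yy, xx]), order=1,
                                   mode="constant", cval=0.0)
    return r, vals


def medial_axis(
    cell_mask: np.ndarray,
    pore_mask: np.ndarray,
    intensity: np.ndarray = None,
    pixel_size: float = None,
    sg_window: int = 11,
    sg_order: int = 3,
    simplify_order: int = 4,
    max_skip_frac: float = 0.2,
) -> tuple[list, dict]:
    """Per-guard-cell medial axes from radial intensity profiles.

    From the pore center of mass, the intensity along a ray at each integer
    degree is scanned for wall peaks; the midline point is the midpoint
    between the pore-border and outer-border maxima. The angular midline is
    Savitzky–Golay smoothed (periodic), junction angles are detected as the
    two midline-intensity maxima (the midline crosses the bright shared
    walls only where the cells meet), and the midline is split there into
    two per-cell arcs, each simplified by a low-order parametric polynomial.

    Returns ([MedialAxis cell1, MedialAxis cell2], info dict with junction
    angles in degrees, the raw midline radius per angle, and skipped
    angles). Raises if more than ``max_skip_frac`` of rays are unusable.
    """
    if pixel_size is None:
        pixel_size = math.sqrt(PIXEL_AREA_UM2)
    cell_mask = np.asarray(cell_mask).astype(bool)
    pore_mask = np.asarray(pore_mask).astype(bool)
    if (cell_mask & pore_mask).any():
        raise MeasurementError("medial_axis", "cell and pore masks overlap")
    if intensity is None:
        intensity = cell_mask.astype(float)
    img = np.asarray(intensity, dtype=float)
    cy, cx = ndimage.center_of_mass(pore_mask)
    r_max = float(np.hypot(*img.shape))

    angles = np.arange(360)
    radii = np.full(360, np.nan)
    widths = np.full(360, np.nan)
    for ang in angles:
        r, vals = _radial_profile(img, (cy, cx), ang, r_max)
        span = vals.max() - vals.min()
        if span < 1e-9:
            continue
        peaks, _ = find_peaks(vals, prominence=0.2 * span)
        # plateaus (unblurred walls) register as flat tops; fall back to runs
        if len(peaks) < 2:
            level = vals.min() + 0.5 * span
            bright = vals > level
            runs = _runs(bright)
            if len(runs) >= 2:
                r1 = r[runs[0]].mean()
                r2 = r[runs[-1]].mean()
            elif len(runs) == 1 and len(runs[0]) >= 2:
                # one solid band (e.g. a filled cell ring): its borders are
                # the half-crossings, located to subpixel by interpolation
                r1 = _subpixel_edge(r, vals, runs[0][0], level, rising=True)
                r2 = _subpixel_edge(r, vals, runs[0][-1], level, rising=False)
            else:
                continue
        else:
            r1, r2 = r[peaks[0]], r[peaks[-1]]
        if r2 - r1 < 1e-6:
            continue
        radii[ang] = 0.5 * (r1 + r2)
        widths[ang] = r2 - r1
    skipped = np.isnan(radii)
    if skipped.mean() > max_skip_frac:
        raise MeasurementError(
            "medial_axis", f"{int(skipped.sum())}/360 rays unusable")
    # fill isolated gaps by periodic interpolation, then smooth
    radii = _interp_periodic(radii)
    widths = _interp_periodic(widths)
    radii_s = savgol_filter(radii, sg_window, sg_order, mode="wrap")

    # junction detection: midline intensity maxima (two, ~opposite)
    mid_y = cy + radii_s * np.sin(np.radians(angles))
    mid_x = cx + radii_s * np.cos(np.radians(angles))
    mid_int = ndimage.map_coordinates(img, np.vstack([mid_y, mid_x]), order=1)
    mid_int_s = savgol_filter(mid_int, 21, 2, mode="wrap")
    j1 = int(np.argmax(mid_int_s))
    away = np.minimum(np.abs(angles - j1), 360 - np.abs(angles - j1)) > 90
    j2_candidates = angles[away]
    j2 = int(j2_candidates[np.argmax(mid_int_s[away])])
    ja, jb = sorted((j1, j2))

    arcs = []
    for sel in (np.arange(ja, jb + 1), np.concatenate(
            [np.arange(jb, 360), np.arange(0, ja + 1)])):
        if len(sel) < simplify_order + 2:
            raise MeasurementError("medial_axis", "arc too short after split")
        px = mid_x[sel] * pixel_size
        py = mid_y[sel] * pixel_size
        tau = np.linspace(0, 1, len(sel))
        cx_fit = np.polyfit(tau, px, simplify_order)
        cy_fit = np.polyfit(tau, py, simplify_order)
        tt = np.linspace(0, 1, 400)
        pts = np.stack([np.polyval(cx_fit, tt), np.polyval(cy_fit, tt)], axis=1)
        arcs.append(MedialAxis(points=pts, arc_length=arc_length(pts)))
    info = {
        "junction_angles_deg": (ja, jb),
        "midline_radius_px": radii_s,
        "midline_width_px": widths,
        "skipped_angles": np.where(skipped)[0],
        "center_px": (cy, cx),
    }
    return arcs, info


def _subpixel_edge(r, vals, idx, level, rising):
    """Linear-interpolated position where ``vals`` crosses ``level`` at the
    edge of a bright run starting/ending at sample ``idx``."""
    j = idx - 1 if rising else idx + 1
    if not 0 <= j < len(vals) or vals[j] == vals[idx]:
        return r[idx]
    frac = (level - vals[j]) / (vals[idx] - vals[j])
    return r[j] + frac * (r[idx] - r[j])


def _runs(mask: np.ndarray):
    """Index arrays of consecutive-True runs."""
    idx = np.where(mask)[0]
    if len(idx) == 0:
        return []
    splits = np.where(np.diff(idx) > 1)[0] + 1
    return np.split(idx, splits)


def _interp_periodic(y: np.ndarray) -> np.ndarray:
    bad = np.isnan(y)
    if not bad.any():
        return y
    x = np.arange(len(y))
    good = ~bad
    y = y.copy()
    y[bad] = np.interp(x[bad], x[good], y[good], period=len(y))
    return y


def arc_length(points: np.ndarray, scale: float = 1.0) -> float:
    """Polyline length: sum of segment lengths × ``scale``.

    Pass points in μm with scale 1 (the default), or in pixels with
    scale = pixel side length. Additive under concatenation and invariant
    under point-order reversal.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need ≥2 points")
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum()) * scale


# ---------------------------------------------------------------------------
# Full measurement pipeline
# ---------------------------------------------------------------------------


def measure_stack(
    stack: ImageStack,
    params: ActiveContourParams | None = None,
) -> StomatalGeometry:
    """Measure the full geometry set of one complex from a z-stack.

    Composes: pore-area profile → robust quartic minimum → pore axes on the
    minimum slice → complex axes near that slice → medial axes and widths.
    ``junction_area`` is left absent (not automated). Stage failures raise
    :class:`MeasurementError` tagged with the failing stage.
    """
    profile = pore_area_profile(stack, params=params)
    min_slice, _, min_area_um2 = robust_min_area(profile, stack.pixel_area_xy)

    seg = segment_active_contour(
        stack.voxels[min_slice],
        np.array([[stack.voxels.shape[1] / 2.0, stack.voxels.shape[2] / 2.0]]),
        params,
    )
    pore_len, pore_wid = component_axes(seg.mask, stack.pixel_size)
    comp_len, comp_wid = complex_dimensions(stack, min_slice, params)

    cell_mask = _segment_complex(stack.voxels[min_slice], params) & ~seg.mask
    arcs, info = medial_axis(
        cell_mask, seg.mask, intensity=stack.voxels[min_slice],
        pixel_size=stack.pixel_size,
    )
    arc_len = float(np.mean([a.arc_length for a in arcs]))
    # guard-cell width: wall-to-wall ray width at each arc midpoint
    jw = info["midline_width_px"]
    ja, jb = info["junction_angles_deg"]
    mid1 = (ja + jb) // 2
    mid2 = (mid1 + 180) % 360
    gc_width = float(np.nanmean([jw[mid1], jw[mid2]])) * stack.pixel_size

    return StomatalGeometry(
        pore_width=pore_wid,
        pore_length=pore_len,
        pore_area=min_area_um2,
        complex_length=comp_len,
        complex_width=comp_wid,
        guard_cell_width=gc_width,
        guard_cell_arc_length=arc_len,
        junction_area=None,
    )
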