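"""Inverse identification of anisotropic guard-cell wall moduli.

A full factorial grid over the six orthotropic moduli (default levels
200 kPa, 200 MPa, 200 GPa — the reported range of plant cell-wall
stiffnesses up to crystalline cellulose) is filtered for physical
admissibility, each candidate is forward-simulated on a set of guard-cell
meshes, and candidates whose simulated open geometries are statistically
indistinguishable from the measured sample (rank-sum p > 0.05) are
accepted. The best candidates are refined by Broyden's quasi-Newton method
against the target pore width, in log-modulus space to preserve positivity.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .meshing import ShellMesh
from .shellfem import (
    LoadCase,
    OrthotropicMaterial,
    SolverSettings,
    solve_nonlinear,
)
from .stats import rank_sum_test

MODULUS_AXES = ("E1", "E2", "E3", "G12", "G13", "G23")

#: Stiffness of crystalline cellulose (MPa) — the biomechanical upper bound.
CELLULOSE_CAP_MPA = 200000.0


@dataclass
class ModulusGrid:
    """Full-factorial search space: the same levels on each of the six
    modulus axes."""

    levels: tuple = (0.2, 200.0, 200000.0)
    axes: tuple = MODULUS_AXES

    def __post_init__(self):
        lv = tuple(float(v) for v in self.levels)
        if len(lv) < 1 or any(v <= 0 for v in lv):
            raise ValueError("levels must be positive")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly increasing")
        self.levels = lv


def enumerate_grid(grid: ModulusGrid, nu: float = 0.003) -> list:
    """Cartesian product over the six modulus axes: levels^6 materials."""
    mats = []
    for combo in itertools.product(grid.levels, repeat=len(grid.axes)):
        kwargs = dict(zip(grid.axes, combo))
        mats.append(OrthotropicMaterial(nu=nu, **kwargs))
    return mats


def filter_feasible(materials, cap: float = CELLULOSE_CAP_MPA) -> list:
    """Keep physically possible materials: positive-definite completed
    stiffness (orthotropic symmetry) and no modulus above the stiffness of
    crystalline cellulose."""
    out = []
    for m in materials:
        if np.all(m.moduli <= cap) and m.is_positive_definite():
            out.append(m)
    return out


@dataclass
class CandidateResult:
    material: OrthotropicMaterial
    geometries: list                      # per-mesh StomatalGeometry (or None)
    p_values: dict = field(default_factory=dict)
    accepted: bool = False
    all_converged: bool = True

    def simulated(self, quantity: str) -> np.ndarray:
        vals = [getattr(g, quantity) for g in self.geometries if g is not None]
        return np.array([v for v in vals if v is not None], dtype=float)


@dataclass
class IdentificationResult:
    accepted_ranges: dict                 # axis -> (min, max) MPa
    optimal: OrthotropicMaterial | None
    candidates: list = field(default_factory=list)
    refinement_trace: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Ranges table: one row per modulus axis with min, max, optimal."""
        rows = []
        for ax in MODULUS_AXES:
            lo, hi = self.accepted_ranges.get(ax, (np.nan, np.nan))
            opt = getattr(self.optimal, ax) if self.optimal is not None else np.nan
            rows.append({"modulus": ax, "min_MPa": lo, "max_MPa": hi,
                         "optimal_MPa": opt})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IdentificationResult":
        ranges = {r["modulus"]: (r["min_MPa"], r["max_MPa"])
                  for _, r in df.iterrows()}
        opt = None
        if not df["optimal_MPa"].isna().any():
            vals = {r["modulus"]: r["optimal_MPa"] for _, r in df.iterrows()}
            opt = OrthotropicMaterial(**vals)
        return cls(accepted_ranges=ranges, optimal=opt)


def _mesh_hash(mesh: ShellMesh) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(mesh.nodes).tobytes())
    h.update(np.ascontiguousarray(mesh.triangles).tobytes())
    h.update(np.ascontiguousarray(mesh.thickness).tobytes())
    return h.hexdigest()


class ForwardCache:
    """Memoizes forward solves by (mesh content, material, load)."""

    def __init__(self):
        self._store = {}
        self._mesh_keys = {}

    def key(self, mesh, material, loadcase, settings):
        mk = self._mesh_keys.get(id(mesh))
        if mk is None:
            mk = _mesh_hash(mesh)
            self._mesh_keys[id(mesh)] = mk
        return (mk, material, loadcase.turgor, loadcase.constraint_mode,
                loadcase.target_complex_length, loadcase.target_complex_width,
                settings.n_increments)

    def get(self, *args):
        return self._store.get(self.key(*args))

    def put(self, result, *args):
        self._store[self.key(*args)] = result


def _forward(mesh, material, loadcase, settings, cache=None):
    if cache is not None:
        hit = cache.get(mesh, material, loadcase, settings)
        if hit is not None:
            return hit
    res = solve_nonlinear(mesh, material, loadcase, settings)
    if cache is not None:
        cache.put(res, mesh, material, loadcase, settings)
    return res


def evaluate_candidates(
    meshes,
    materials,
    loadcase: LoadCase,
    measured,
    quantities: tuple = ("pore_width",),
    alpha: float = 0.05,
    settings: SolverSettings | None = None,
    cache: ForwardCache | None = None,
    progress: bool = False,
) -> list:
    """Forward-simulate every candidate on every mesh and test acceptance.

    ``measured`` maps quantity name -> measured open-state sample (array);
    a DataFrame works too. A candidate is accepted when every tested
    quantity gives rank-sum p > ``alpha``; any non-converged solve
    disqualifies (but keeps) the candidate.
    """
    if len(meshes) < 2:
        raise ValueError("need ≥2 meshes")
    if settings is None:
        settings = SolverSettings()
    if isinstance(measured, pd.DataFrame):
        measured = {q: measured[q].to_numpy(dtype=float) for q in quantities}
    for q in quantities:
        if len(np.asarray(measured[q])) < 2:
            raise ValueError(f"measured sample for {q!r} needs ≥2 values")
    out = []
    iterator = materials
    if progress:
        from tqdm import tqdm
        iterator = tqdm(materials, desc="candidates")
    for mat in iterator:
        geoms, converged = [], True
        for mesh in meshes:
            res = _forward(mesh, mat, loadcase, settings, cache)
            if not res.converged or res.deformed_geometry is None:
                converged = False
                geoms.append(None)
            else:
                geoms.append(res.deformed_geometry)
        cand = CandidateResult(material=mat, geometries=geoms,
                               all_converged=converged)
        if converged:
            ok = True
            for q in quantities:
                sim = cand.simulated(q)
                r = rank_sum_test(np.asarray(measured[q], dtype=float), sim)
                cand.p_values[q] = r.p
                ok = ok and (r.p > alpha)
            cand.accepted = ok
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Broyden refinement
# ---------------------------------------------------------------------------


def broyden_root(f, x0, tol: float = 1e-6, max_iter: int = 50,
                 rel_step: float = 0.05):
    """Derivative-free quasi-Newton root finding for f: R^k → R.

    The Jacobian row is seeded by forward differences and updated by
    Broyden's rank-one formula; steps are halved while they fail to reduce
    |f|. Returns (x, trace, converged); trace rows are (x, f(x)).
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    k = len(x)
    fx = float(f(x))
    trace = [(x.copy(), fx)]
    if abs(fx) <= tol:
        return x, trace, True
    J = np.empty(k)
    for i in range(k):
        h = rel_step * max(abs(x[i]), 1e-8)
        xp = x.copy()
        xp[i] += h
        J[i] = (float(f(xp)) - fx) / h
    for _ in range(max_iter):
        nJ = float(J @ J)
        if nJ < 1e-30:
            return x, trace, False
        dx = -fx * J / nJ  # least-norm quasi-Newton step
        alpha = 1.0
        x_new, f_new = None, None
        for _ in range(8):
            cand = x + alpha * dx
            fc = float(f(cand))
            if np.isfinite(fc) and abs(fc) < abs(fx):
                x_new, f_new = cand, fc
                break
            alpha *= 0.5
        if x_new is None:
            return x, trace, False  # stagnation
        s = x_new - x
        J = J + (f_new - fx - J @ s) * s / float(s @ s)
        x, fx = x_new, f_new
        trace.append((x.copy(), fx))
        if abs(fx) <= tol:
            return x, trace, True
    return x, trace, False


def refine_broyden(
    start: OrthotropicMaterial,
    free_axes,
    meshes,
    target_pore_width: float,
    loadcase: LoadCase | None = None,
    settings: SolverSettings | None = None,
    tol: float = 0.05,
    max_iter: int = 25,
    cache: ForwardCache | None = None,
):
    """Refine moduli so the mean simulated pore width hits the target.

    Root-finds r(m) = mean simulated pore width − target over the chosen
    modulus axes with Broyden's method, parameterized in log-modulus space
    so iterates stay positive; candidates with an indefinite stiffness are
    rejected inside the line search. Terminates at |r| < ``tol`` μm (default
    0.05) or ``max_iter`` iterations; on stagnation the best iterate is
    returned with converged=False.
    """
    if loadcase is None:
        loadcase = LoadCase()
    if settings is None:
        settings = SolverSettings()
    if not start.is_positive_definite():
        raise ValueError("start material is not feasible")
    free_axes = tuple(free_axes)
    cache = cache if cache is not None else ForwardCache()

    def material_at(logm):
        vals = {ax: float(np.exp(v)) for ax, v in zip(free_axes, logm)}
        return replace(start, **vals)

    def residual(logm):
        mat = material_at(logm)
        if not mat.is_positive_definite():
            return np.inf
        widths = []
        for mesh in meshes:
            res = _forward(mesh, mat, loadcase, settings, cache)
            if not res.converged or res.deformed_geometry is None:
                return np.inf
            widths.append(res.deformed_geometry.pore_width)
        return float(np.mean(widths) - target_pore_width)

    x0 = np.log([getattr(start, ax) for ax in free_axes])
    x, trace, converged = broyden_root(residual, x0, tol=tol, max_iter=max_iter)
    best = material_at(x)
    nice_trace = [{"moduli": {ax: float(np.exp(v))
                              for ax, v in zip(free_axes, xx)},
                   "residual_um": float(r)} for xx, r in trace]
    return best, nice_trace, converged


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


def summarize(
    candidates,
    refined=None,
    measured_means: dict | None = None,
    quantities: tuple = ("pore_width",),
    refinement_trace=None,
) -> IdentificationResult:
    """Collapse accepted candidates into per-modulus ranges and pick the
    optimal material.

    The optimal set is the refined (or accepted) material with the smallest
    aggregate geometry mismatch — the sum of squared relative errors of the
    simulated means against the measured means over the configured
    quantities. Ties break deterministically toward the lowest E1, then E2,
    and so on.
    """
    accepted = [c for c in candidates if c.accepted]
    ranges = {}
    if accepted:
        for ax in MODULUS_AXES:
            vals = [getattr(c.material, ax) for c in accepted]
            ranges[ax] = (float(min(vals)), float(max(vals)))

    def mismatch(cand: CandidateResult) -> float:
        if measured_means is None:
            return 0.0
        total = 0.0
        for q in quantities:
            sim = cand.simulated(q)
            if len(sim) == 0:
                return np.inf
            ref = measured_means[q]
            total += ((sim.mean() - ref) / ref) ** 2
        return total

    pool = list(accepted)
    if refined is not None:
        pool = list(refined) + pool
    optimal = None
    if pool:
        def sort_key(c):
            mat = c.material if isinstance(c, CandidateResult) else c
            mm = mismatch(c) if isinstance(c, CandidateResult) else 0.0
            return (mm,) + tuple(getattr(mat, ax) for ax in MODULUS_AXES)
        pool_c = [c for c in pool if isinstance(c, CandidateResult)]
        pool_m = [c for c in pool if not isinstance(c, CandidateResult)]
        if pool_m:
            optimal = sorted(pool_m,
                             key=lambda m: tuple(getattr(m, ax)
                                                 for ax in MODULUS_AXES))[0]
        else:
            optimal = sorted(pool_c, key=sort_key)[0].material
    return IdentificationResult(
        accepted_ranges=ranges,
        optimal=optimal,
        candidates=candidates,
        refinement_trace=refinement_trace or [],
    )
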