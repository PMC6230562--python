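"""Model/Results interface to guard-cell mechanics identification.

``StomatalMechanicsModel`` bundles the data of one identification problem —
guard-cell shell meshes in the closed state plus a measured open-state
geometry sample — and exposes ``fit()`` (factorial screening, feasibility
filtering, rank-sum acceptance, Broyden refinement) returning a
``StomatalMechanicsResults`` with the identified moduli, their accepted
ranges, per-candidate diagnostics, and a ``summary()`` table. Forward
simulation hangs off both objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import identify as _id
from .identify import (
    CELLULOSE_CAP_MPA,
    ForwardCache,
    IdentificationResult,
    ModulusGrid,
    MODULUS_AXES,
)
from .shellfem import LoadCase, OrthotropicMaterial, SolverSettings


class StomatalMechanicsModel:
    """Inverse wall-modulus identification for one genotype.

    Parameters
    ----------
    meshes : list of ShellMesh
        Closed-state guard-cell pair meshes (several per genotype to carry
        biological variability).
    measured : DataFrame or dict
        Measured open-state geometry sample; must contain every tested
        quantity (default: pore_width) as a column/key.
    loadcase : LoadCase, optional
        Default: 5 MPa turgor, no pavement-cell constraints.
    grid : ModulusGrid, optional
        Factorial search space (default levels 0.2 / 200 / 200000 MPa).
    quantities : tuple of str
        Geometry quantities tested for acceptance (p > alpha on each).
    """

    def __init__(self, meshes, measured, loadcase=None, grid=None,
                 quantities=("pore_width",), alpha=0.05, settings=None,
                 cap=CELLULOSE_CAP_MPA):
        if len(meshes) < 2:
            raise ValueError("need ≥2 meshes")
        self.meshes = list(meshes)
        if isinstance(measured, dict):
            measured = pd.DataFrame(measured)
        self.measured = measured
        missing = [q for q in quantities if q not in measured.columns]
        if missing:
            raise ValueError(f"measured sample missing columns {missing}")
        self.loadcase = loadcase or LoadCase()
        self.grid = grid or ModulusGrid()
        self.quantities = tuple(quantities)
        self.alpha = float(alpha)
        self.settings = settings or SolverSettings()
        self.cap = cap
        self.cache = ForwardCache()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meshes, genotype=None,
                       state="open", **kwargs):
        """Build from a geometry table with ``genotype``/``state`` columns
        (the synthetic-table schema)."""
        sub = df
        if genotype is not None and "genotype" in df.columns:
            sub = sub[sub["genotype"] == genotype]
        if "state" in sub.columns:
            sub = sub[sub["state"] == state]
        if len(sub) < 2:
            raise ValueError("selected measured sample has fewer than 2 rows")
        return cls(meshes, sub.reset_index(drop=True), **kwargs)

    # ------------------------------------------------------------------
    def simulate(self, material: OrthotropicMaterial, mesh_index=None):
        """Forward-solve the load case; returns one SimulationResult per
        mesh (or for one mesh if ``mesh_index`` given)."""
        meshes = (self.meshes if mesh_index is None
                  else [self.meshes[mesh_index]])
        return [_id._forward(m, material, self.loadcase, self.settings,
                             self.cache) for m in meshes]

    def fit(self, refine=True, free_axes=("E1",), broyden_tol=0.05):
        """Run the identification pipeline and return results.

        Steps: enumerate the factorial grid, drop physically impossible
        sets, forward-simulate and rank-sum-test every candidate, then (if
        ``refine``) polish the best accepted candidate with Broyden's method
        against the measured mean pore width.
        """
        materials = _id.filter_feasible(_id.enumerate_grid(self.grid),
                                        self.cap)
        candidates = _id.evaluate_candidates(
            self.meshes, materials, self.loadcase, self.measured,
            quantities=self.quantities, alpha=self.alpha,
            settings=self.settings, cache=self.cache)
        measured_means = {q: float(self.measured[q].mean())
                          for q in self.quantities}

        refined_cands, trace = None, None
        if refine:
            seed_result = _id.summarize(candidates,
                                        measured_means=measured_means,
                                        quantities=self.quantities)
            start = seed_result.optimal
            if start is not None:
                target = measured_means.get("pore_width")
                refined_mat, trace, _ = _id.refine_broyden(
                    start, free_axes, self.meshes, target,
                    loadcase=self.loadcase, settings=self.settings,
                    tol=broyden_tol, cache=self.cache)
                refined_cands = _id.evaluate_candidates(
                    self.meshes, [refined_mat], self.loadcase, self.measured,
                    quantities=self.quantities, alpha=self.alpha,
                    settings=self.settings, cache=self.cache)

        ident = _id.summarize(candidates, refined=refined_cands,
                              measured_means=measured_means,
                              quantities=self.quantities,
                              refinement_trace=trace)
        return StomatalMechanicsResults(model=self, ident=ident)


@dataclass
class StomatalMechanicsResults:
    """Identified wall moduli with acceptance diagnostics."""

    model: StomatalMechanicsModel
    ident: IdentificationResult

    @property
    def params(self) -> OrthotropicMaterial | None:
        """The optimal material (smallest aggregate geometry mismatch)."""
        return self.ident.optimal

    @property
    def accepted_ranges(self) -> dict:
        return self.ident.accepted_ranges

    @property
    def candidates(self):
        return self.ident.candidates

    @property
    def n_accepted(self) -> int:
        return sum(1 for c in self.ident.candidates if c.accepted)

    def simulate(self, material=None):
        """Forward simulation at the fitted (or a given) material."""
        mat = material or self.params
        if mat is None:
            raise ValueError("no accepted material to simulate")
        return self.model.simulate(mat)

    def to_frame(self) -> pd.DataFrame:
        return self.ident.to_frame()

    def summary(self) -> str:
        """Plain-text summary table of ranges and the optimal set."""
        lines = ["Guard-cell wall modulus identification",
                 "=" * 54,
                 f"meshes: {len(self.model.meshes)}   "
                 f"measured n: {len(self.model.measured)}   "
                 f"grid: {len(self.model.grid.levels)}^6 levels",
                 f"quantities: {', '.join(self.model.quantities)}   "
                 f"alpha: {self.model.alpha}",
                 f"accepted candidates: {self.n_accepted}",
                 "-" * 54,
                 f"{'modulus':>8} {'min (MPa)':>12} {'max (MPa)':>12} "
                 f"{'optimal':>12}"]
        for ax in MODULUS_AXES:
            lo, hi = self.ident.accepted_ranges.get(ax, (np.nan, np.nan))
            opt = getattr(self.ident.optimal, ax) if self.ident.optimal else np.nan
            lines.append(f"{ax:>8} {lo:>12.4g} {hi:>12.4g} {opt:>12.4g}")
        lines.append("=" * 54)
        return "\n".join(lines)
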