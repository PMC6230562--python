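"""End-to-end orchestration: synthetic data → morphometry → meshing →
simulation → identification → report bundle, with a validated run
configuration and deterministic seeding."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .meshing import export_mesh
from .shellfem import LoadCase, OrthotropicMaterial, SolverSettings, solve_nonlinear
from .identify import ModulusGrid
from .model import StomatalMechanicsModel
from .stats import rank_sum_test

#: Wild-type orthotropic constants (MPa) converted from published
#: hyperelastic wall properties; the baseline forward-model material.
COL0_WALL_CONSTANTS = OrthotropicMaterial(E1=99.0, E2=601.0, E3=601.0,
                                  G12=33.0, G13=33.0, G23=33.0)


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run.

    Defaults marked (published) come from the study conditions; the rest are
    implementation choices.
    """

    genotype: str = "Col-0"
    state_closed: str = "closed"
    state_open: str = "open"
    turgor: float = 5.0                  # MPa (published)
    wall_thickness: float = 0.5          # μm, simplified model (published)
    resolution: tuple = (48, 32)         # torus mesh rings × ring points
    n_meshes: int = 3
    n_measured: int = 10
    grid_levels: tuple = (0.2, 200.0, 200000.0)   # MPa (published)
    accept_p: float = 0.05               # (published)
    n_increments: int = 10
    newton_tol: float = 1e-6
    seed: int = 0
    constraint_mode: str = "none"
    out_dir: str = "stomech_run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for key in ("resolution", "grid_levels"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @property
    def digest(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


def compare_geometries(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-quantity rank-sum comparison of two geometry tables.

    Returns one row per shared numeric column with U, two-sided p, and a
    significance flag at ``alpha``.
    """
    shared = [c for c in table_a.columns
              if c in table_b.columns
              and np.issubdtype(table_a[c].dtype, np.number)
              and np.issubdtype(table_b[c].dtype, np.number)]
    if not shared:
        raise ValueError("tables share no numeric columns")
    rows = []
    for col in shared:
        a = table_a[col].dropna().to_numpy(dtype=float)
        b = table_b[col].dropna().to_numpy(dtype=float)
        if len(a) < 1 or len(b) < 1:
            continue
        r = rank_sum_test(a, b)
        rows.append({"quantity": col, "U": r.U, "p": r.p,
                     "method": r.method, "significant": r.p < alpha})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig | dict, progress: bool = False) -> dict:
    """Execute the full analysis as configured and write the report bundle.

    Stages: synthetic geometry table → parametric closed-state meshes →
    demo forward simulation (baseline wild-type material) → identification
    against the open-state sample. Partial outputs are preserved on stage
    failure; the manifest records the failure point.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": json.loads(config.to_json()),
                "config_digest": config.digest, "stages": {}}
    bundle = {"config": config, "out_dir": out}
    rng = np.random.default_rng(config.seed)

    def _stage(name, fn):
        t0 = time.time()
        try:
            value = fn()
        except Exception as exc:  # record and re-raise after writing manifest
            manifest["stages"][name] = {"status": "failed", "error": str(exc),
                                        "seconds": round(time.time() - t0, 2)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.time() - t0, 2)}
        return value

    # 1. synthetic measured-geometry table
    def make_table():
        table = synth.generate_geometry_table(n=config.n_measured,
                                              seed=config.seed)
        table.to_csv(out / "geometry_table.csv", index=False)
        return table
    table = _stage("synth_table", make_table)
    bundle["geometry_table"] = table

    # 2. closed-state meshes for the genotype (jittered parametric tori)
    def make_meshes():
        base = synth.ParametricComplex.from_published(
            config.genotype, config.state_closed,
            wall_thickness=config.wall_thickness)
        meshes = []
        for i in range(config.n_meshes):
            scale = 1.0 if i == 0 else float(rng.normal(1.0, 0.03))
            params = synth.ParametricComplex(
                pore_width=base.pore_width * scale,
                pore_length=base.pore_length * scale,
                complex_length=base.complex_length * scale,
                complex_width=base.complex_width * scale,
                guard_cell_width=base.guard_cell_width * scale,
                wall_thickness=base.wall_thickness)
            meshes.append(synth.generate_torus_complex(
                params, resolution=config.resolution))
        export_mesh(meshes[0], out / "mesh_closed.vtk")
        return meshes
    meshes = _stage("meshing", make_meshes)
    bundle["meshes"] = meshes

    # 3. baseline forward simulation (wild-type constants)
    def forward():
        settings = SolverSettings(n_increments=config.n_increments,
                                  newton_tol=config.newton_tol)
        lc = LoadCase(turgor=config.turgor,
                      constraint_mode=config.constraint_mode,
                      target_complex_length=(
                          synth.PUBLISHED_GEOMETRY[(config.state_open, config.genotype)]
                          ["complex_length"][0]
                          if config.constraint_mode == "complex-dims" else None),
                      target_complex_width=(
                          synth.PUBLISHED_GEOMETRY[(config.state_open, config.genotype)]
                          ["complex_width"][0]
                          if config.constraint_mode == "complex-dims" else None))
        res = solve_nonlinear(meshes[0], COL0_WALL_CONSTANTS, lc, settings)
        from .synth import measure_mesh_dimensions
        initial = measure_mesh_dimensions(meshes[0])
        report = {
            "initial_pore_width_um": initial["pore_width"],
            "final_pore_width_um": (res.deformed_geometry.pore_width
                                    if res.deformed_geometry else None),
            "converged": bool(res.converged),
            "junction_loading_MPa": res.junction_loading,
            "dorsal_loading_MPa": res.dorsal_loading,
        }
        (out / "forward_demo.json").write_text(json.dumps(report, indent=2))
        from ._vtk import write_vtk
        write_vtk(out / "deformed.vtk", meshes[0].nodes + res.displacements,
                  meshes[0].triangles,
                  cell_scalars={"thickness": meshes[0].thickness},
                  cell_vectors={"strain": res.strain, "stress": res.stress},
                  point_vectors={"displacement": res.displacements})
        return report
    bundle["forward_demo"] = _stage("forward_demo", forward)

    # 4. identification against the open-state sample
    def identify_stage():
        measured = table[(table["genotype"] == config.genotype)
                         & (table["state"] == config.state_open)]
        settings = SolverSettings(n_increments=config.n_increments,
                                  newton_tol=config.newton_tol)
        model = StomatalMechanicsModel(
            meshes, measured.reset_index(drop=True),
            loadcase=LoadCase(turgor=config.turgor),
            grid=ModulusGrid(levels=config.grid_levels),
            alpha=config.accept_p, settings=settings)
        results = model.fit(refine=True)
        results.to_frame().to_csv(out / "moduli_ranges.csv", index=False)
        rows = []
        for c in results.candidates:
            row = {ax: getattr(c.material, ax)
                   for ax in ("E1", "E2", "E3", "G12", "G13", "G23")}
            row.update({"accepted": c.accepted,
                        "converged": c.all_converged,
                        **{f"p_{k}": v for k, v in c.p_values.items()}})
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "candidates.csv", index=False)
        (out / "refinement_trace.json").write_text(
            json.dumps(results.ident.refinement_trace, indent=2))
        return results
    bundle["results"] = _stage("identify", identify_stage)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
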