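"""Shared fixtures: expensive synthetic artifacts are built once per session."""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("det", derandomize=True)
hyp_settings.load_profile("det")

from stomech import synth
from stomech.meshing import ShellMesh, assign_material_frames
from stomech.shellfem import (
    LoadCase,
    OrthotropicMaterial,
    SolverSettings,
    solve_nonlinear,
)


@pytest.fixture(scope="session")
def col0_closed():
    return synth.ParametricComplex.from_published("Col-0", "closed")


@pytest.fixture(scope="session")
def wildtype_wall_material():
    return OrthotropicMaterial(E1=99.0, E2=601.0, E3=601.0,
                               G12=33.0, G13=33.0, G23=33.0)


@pytest.fixture(scope="session")
def noiseless_stack(col0_closed):
    truth = synth.GroundTruth(geometry={}, rng_seed=7)
    return synth.generate_stack(col0_closed, truth)


@pytest.fixture(scope="session")
def col0_mesh_coarse(col0_closed):
    return synth.generate_torus_complex(col0_closed, (32, 24))


@pytest.fixture(scope="session")
def sphere_mesh():
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    mesh = ShellMesh(nodes=np.asarray(ico.vertices, dtype=float),
                     triangles=np.asarray(ico.faces, dtype=int),
                     thickness=np.full(len(ico.faces), 0.5))
    assign_material_frames(mesh)
    return mesh


@pytest.fixture(scope="session")
def worked_example_result(col0_closed, wildtype_wall_material):
    """The simplified wild-type opening simulation: closed-state torus,
    published orthotropic constants, 5 MPa follower pressure, free complex."""
    mesh = synth.generate_torus_complex(col0_closed, (48, 32))
    res = solve_nonlinear(mesh, wildtype_wall_material, LoadCase(turgor=5.0),
                          SolverSettings(n_increments=10))
    return mesh, res
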