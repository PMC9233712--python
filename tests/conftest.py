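"""Shared fixtures: small meshes, a hand-built T1 quartet, and the
session-scoped small-preset sweep reused by the slow simulation tests."""

import math

import numpy as np
import pytest

from epiextrude import ModelParams, build_initial_tissue, select_tracked_cells
from epiextrude.experiments import run_sweep
from epiextrude.vertex_core import CellFace, TissueMesh


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture()
def hexagon_mesh() -> TissueMesh:
    """One regular hexagonal cell with area exactly 1."""
    s = math.sqrt(2 / (3 * math.sqrt(3)))
    verts = np.array(
        [[s * math.cos(a), s * math.sin(a)] for a in np.arange(6) * math.pi / 3]
    )
    return TissueMesh(verts, [CellFace(list(range(6)), 1.0, 0.02)])


@pytest.fixture()
def square_mesh() -> TissueMesh:
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return TissueMesh(verts, [CellFace([0, 1, 2, 3], 1.0, 0.02)])


@pytest.fixture()
def quartet_mesh() -> TissueMesh:
    """Four cells around a short central vertical edge of length 0.15:
    two quads (left/right) sharing it, a triangle above and below."""
    verts = np.array(
        [
            [0.0, 0.075],  # 0 = i
            [0.0, -0.075],  # 1 = j
            [-1.0, 0.8],  # 2
            [-1.0, -0.8],  # 3
            [1.0, 0.8],  # 4
            [1.0, -0.8],  # 5
        ]
    )
    faces = [
        CellFace([0, 2, 3, 1], 1.0, 0.02),  # left quad (CCW)
        CellFace([1, 5, 4, 0], 1.0, 0.02),  # right quad
        CellFace([0, 4, 2], 1.0, 0.02),  # top triangle
        CellFace([1, 3, 5], 1.0, 0.02),  # bottom triangle
    ]
    return TissueMesh(verts, faces)


@pytest.fixture(scope="session")
def small_tissue():
    """A 300-cell tissue with 10 tracked interior cells (built once)."""
    mesh = build_initial_tissue(300, 0)
    tracked = select_tracked_cells(mesh, 10, 10_000)
    return mesh, tuple(tracked)


@pytest.fixture(scope="session")
def small_sweep():
    """The full published condition/rate grid on the desk-scale preset,
    5 paired seeds — shared by the regime, dose-response and control
    stability tests."""
    return run_sweep(seeds=range(5), preset="small")
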