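"""Shared fixtures: meshes, grids and an independent brute-force RVI oracle."""

from __future__ import annotations

import numpy as np
import pytest

from rvimap.geometry import (
    InfarctSpec,
    LabeledMesh,
    RecordingGrid,
    build_idealized_infarct_sheet,
)


@pytest.fixture(scope="session")
def default_mesh() -> LabeledMesh:
    """The full-size idealized infarct sheet (40 x 40 mm at 0.2 mm)."""
    return build_idealized_infarct_sheet()


@pytest.fixture(scope="session")
def small_infarct_mesh() -> LabeledMesh:
    """Geometrically scaled-down infarct sheet for fast simulation tests."""
    spec = InfarctSpec(sheet_size=(20.0, 20.0), resolution=0.4,
                       scar_radius=7.0, bz_radius=7.5, isthmus_width=3.0)
    return build_idealized_infarct_sheet(spec)


@pytest.fixture()
def regular_grid_2d():
    """0.5 mm regular electrode lattice on [0, 20]^2 as a bare point grid."""
    xs = np.arange(0.0, 20.0 + 1e-9, 0.5)
    X, Y = np.meshgrid(xs, xs)
    return RecordingGrid.from_points(np.column_stack([X.ravel(), Y.ravel()]))


def brute_force_rvi_maps(markers, grid, radius, mesh=None):
    """O(n^2) reference implementation of all three interpolation methods.

    Deliberately naive: explicit double loop, explicit distance checks, and a
    linear scan for nearest mesh nodes (first minimum = lowest index).
    Returns (minimum, average, nearest_neighbor-or-None) value arrays.
    """
    at, rt = markers.at, markers.rt
    pos = grid.electrodes
    n = grid.n_electrodes
    per_site: list[list[float]] = [[] for _ in range(n)]
    nn_acc: dict[int, list[float]] = {}
    for i in range(n):
        for j in range(n):
            if i == j or np.isnan(at[i]) or np.isnan(at[j]) or np.isnan(rt[i]):
                continue
            if not (at[j] > at[i]):
                continue
            if np.linalg.norm(pos[i] - pos[j]) > radius:
                continue
            v = rt[i] - at[j]
            per_site[i].append(v)
            if mesh is not None:
                mid = 0.5 * (pos[i] + pos[j])
                k = int(np.argmin(np.linalg.norm(mesh.nodes - mid, axis=1)))
                nn_acc.setdefault(k, []).append(v)
    minimum = np.array([min(v) if v else np.nan for v in per_site])
    average = np.array([float(np.mean(v)) if v else np.nan for v in per_site])
    nearest = None
    if mesh is not None:
        nearest = np.full(mesh.n_nodes, np.nan)
        for k, vals in nn_acc.items():
            nearest[k] = float(np.mean(vals))
    return minimum, average, nearest
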