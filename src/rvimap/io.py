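"""CSV and legacy-VTK export/import for meshes, grids, markers and RVI maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import REGION_NAMES, LabeledMesh, RecordingGrid
from .markers import MarkerMap

__all__ = [
    "write_mesh_vtk",
    "write_mesh_csv",
    "write_grid_csv",
    "write_markers_csv",
    "read_markers_csv",
    "write_rvimap_csv",
    "write_rvimap_vtk",
    "write_traces_csv",
]

_REGION_CODE = {name: code for code, name in REGION_NAMES.items()}


def _vtk_header(f, title: str) -> None:
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\n")
    f.write("DATASET UNSTRUCTURED_GRID\n")


def _vtk_points(f, points: np.ndarray) -> None:
    f.write(f"POINTS {points.shape[0]} float\n")
    pts3 = np.zeros((points.shape[0], 3))
    pts3[:, : points.shape[1]] = points
    for p in pts3:
        f.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")


def _vtk_point_data(f, n: int, fields: dict[str, np.ndarray]) -> None:
    f.write(f"POINT_DATA {n}\n")
    for name, values in fields.items():
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        for v in values:
            f.write(f"{float(v):.6g}\n")


def write_mesh_vtk(mesh: LabeledMesh, path: str | Path,
                   extra_point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the labeled mesh as legacy ASCII VTK with per-node region labels."""
    cell_type = {4: 9, 2: 3}[mesh.elements.shape[1]]  # VTK_QUAD / VTK_LINE
    with open(path, "w") as f:
        _vtk_header(f, "rvimap labeled mesh")
        _vtk_points(f, mesh.nodes)
        m, k = mesh.elements.shape
        f.write(f"CELLS {m} {m * (k + 1)}\n")
        for el in mesh.elements:
            f.write(f"{k} " + " ".join(str(int(i)) for i in el) + "\n")
        f.write(f"CELL_TYPES {m}\n")
        f.write("\n".join([str(cell_type)] * m) + "\n")
        fields = {"region": mesh.region.astype(float), "node_area": mesh.node_area}
        fields.update(extra_point_data or {})
        _vtk_point_data(f, mesh.n_nodes, fields)


def write_mesh_csv(mesh: LabeledMesh, path: str | Path) -> None:
    df = pd.DataFrame({"x": mesh.nodes[:, 0], "y": mesh.nodes[:, 1],
                       "region": [REGION_NAMES[r] for r in mesh.region]})
    df.to_csv(path, index=False)


def write_grid_csv(grid: RecordingGrid, path: str | Path) -> None:
    df = pd.DataFrame({
        "electrode_id": np.arange(grid.n_electrodes),
        "x": grid.electrodes[:, 0],
        "y": grid.electrodes[:, 1],
        "host_node": grid.host_node,
        "cluster_id": grid.cluster_id if grid.cluster_id is not None
        else np.zeros(grid.n_electrodes, dtype=int),
        "kind": grid.kind,
    })
    df.to_csv(path, index=False)


def write_markers_csv(maps: list[MarkerMap], grid: RecordingGrid | None,
                      path: str | Path) -> None:
    """Marker maps as CSV rows (electrode_id, beat, AT, RT), NA for undefined."""
    frames = []
    for m in maps:
        df = m.to_frame()
        if grid is not None:
            df.insert(1, "x", grid.electrodes[:, 0])
            df.insert(2, "y", grid.electrodes[:, 1])
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, na_rep="NA")


def read_markers_csv(path: str | Path) -> tuple[RecordingGrid, dict[str, MarkerMap]]:
    """Read an AT/RT marker table on an arbitrary electrode point set.

    Expects columns electrode_id, x, y, beat, AT, RT (NA = undefined); returns
    the electrode set as a free-floating grid plus one marker map per beat.
    """
    df = pd.read_csv(path, na_values=["NA"])
    required = {"electrode_id", "x", "y", "beat", "AT", "RT"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker CSV must have columns {sorted(required)}")
    ids = np.sort(df["electrode_id"].unique())
    first = df.drop_duplicates("electrode_id").set_index("electrode_id").loc[ids]
    grid = RecordingGrid.from_points(first[["x", "y"]].to_numpy())
    maps = {}
    for beat, sub in df.groupby("beat", sort=False):
        sub = sub.set_index("electrode_id").reindex(ids)
        maps[str(beat)] = MarkerMap(beat=str(beat),
                                    at=sub["AT"].to_numpy(float),
                                    rt=sub["RT"].to_numpy(float))
    return grid, maps


def write_rvimap_csv(rvimap, path: str | Path) -> None:
    rvimap.to_frame().to_csv(path, index=False, na_rep="NA")


def write_rvimap_vtk(rvimap, mesh: LabeledMesh, path: str | Path) -> None:
    """Node-indexed RVI map as VTK point data on its mesh (NaN -> large flag)."""
    if rvimap.site_kind != "mesh_node":
        raise ValueError("VTK export needs a node-indexed (nearest-neighbor) map")
    values = np.where(np.isnan(rvimap.values), 1e30, rvimap.values)
    write_mesh_vtk(mesh, path, extra_point_data={"rvi": values})


def write_traces_csv(result, grid: RecordingGrid, path: str | Path) -> None:
    cols = {"time_ms": result.times}
    for e in range(grid.n_electrodes):
        cols[f"e{e}"] = result.traces[:, e]
    pd.DataFrame(cols).to_csv(path, index=False)
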