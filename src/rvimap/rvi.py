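"""The re-entry vulnerability index (RVI) and its global map constructions.

For a pair of recording sites, RVI(i, j) = RT(i) - AT(j), where j is a
*downstream neighbor* of i: a site within a search radius R that activates
strictly later.  The index measures the margin between the repolarization of
the tissue proximal to a (potential) line of block and the arrival of the
wavefront on the distal side; small or negative values flag susceptibility to
re-entry.

Three global interpolation schemes turn pairwise values into a map:

* ``nearest_neighbor`` — each RVI(i, j) is deposited on the mesh node nearest
  the geometric midpoint of i and j; nodes hit by several pairs take the mean.
* ``average`` — site i takes the mean over all of its downstream pairs.
* ``minimum`` — site i takes the minimum over all of its downstream pairs.

The vulnerable region is the set of sites with RVI strictly below a threshold
(50 ms by default); its size is the sum of the per-site areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import LabeledMesh, RecordingGrid
from .markers import MarkerMap

__all__ = [
    "METHODS",
    "VULNERABILITY_THRESHOLD_MS",
    "RVIConfig",
    "RVIMap",
    "downstream_pairs",
    "rvi_pair",
    "build_map",
    "VulnerableRegion",
    "quantify_vulnerable_region",
    "sweep",
]

METHODS = ("nearest_neighbor", "average", "minimum")

#: Default absolute vulnerability threshold (ms): sites with RVI < 50 ms are
#: counted as part of the vulnerable region.
VULNERABILITY_THRESHOLD_MS = 50.0


@dataclass(frozen=True)
class RVIConfig:
    """Search radius, interpolation method and vulnerability threshold."""

    radius: float = 4.0
    method: str = "minimum"
    vulnerability_threshold: float = VULNERABILITY_THRESHOLD_MS

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("search radius must be positive")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not np.isfinite(self.vulnerability_threshold):
            raise ValueError("vulnerability threshold must be finite")


@dataclass
class RVIMap:
    """Per-site RVI values (ms); NaN marks sites with no downstream pair.

    ``site_kind`` is ``"electrode"`` for the average/minimum methods and
    ``"mesh_node"`` for nearest-neighbor maps (values live on mesh nodes
    nearest to pair midpoints).
    """

    values: np.ndarray
    site_kind: str
    positions: np.ndarray
    config: RVIConfig
    beat: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        cols = {"site_id": np.arange(self.values.size)}
        for k, name in enumerate("xyz"[: self.positions.shape[1]]):
            cols[name] = self.positions[:, k]
        cols["rvi"] = self.values
        return pd.DataFrame(cols)


def rvi_pair(rt_i: float, at_j: float) -> float:
    """Pairwise index RVI(i, j) = RT(i) - AT(j); NaN if either is undefined."""
    return rt_i - at_j


def downstream_pairs(markers: MarkerMap, grid: RecordingGrid, radius: float
                     ) -> np.ndarray:
    """All directed pairs (i, j) with j a downstream neighbor of i.

    A pair is included iff AT(i) and AT(j) are both defined, AT(j) > AT(i)
    strictly, and the Euclidean electrode distance is <= radius.  Returns an
    (P, 2) integer array (possibly empty).
    """
    if markers.n_sites != grid.n_electrodes:
        raise ValueError("marker map and grid cover different electrode sets")
    at = markers.at
    tree = cKDTree(grid.electrodes)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=int)
    a, b = pairs[:, 0], pairs[:, 1]
    ok = ~np.isnan(at[a]) & ~np.isnan(at[b]) & (at[a] != at[b])
    a, b = a[ok], b[ok]
    swap = at[a] > at[b]
    i = np.where(swap, b, a)
    j = np.where(swap, a, b)
    return np.column_stack([i, j])


def build_map(markers: MarkerMap, grid: RecordingGrid, config: RVIConfig,
              mesh: LabeledMesh | None = None) -> RVIMap:
    """Construct a global RVI map with the configured interpolation method."""
    pairs = downstream_pairs(markers, grid, config.radius)
    pair_rvi = markers.rt[pairs[:, 0]] - markers.at[pairs[:, 1]]
    # pairs whose proximal RT is undefined contribute nothing
    ok = ~np.isnan(pair_rvi)
    pairs, pair_rvi = pairs[ok], pair_rvi[ok]

    if config.method == "nearest_neighbor":
        if mesh is None:
            raise ValueError("nearest_neighbor interpolation requires a mesh")
        values = np.full(mesh.n_nodes, np.nan)
        if len(pairs):
            mid = 0.5 * (grid.electrodes[pairs[:, 0]] + grid.electrodes[pairs[:, 1]])
            host = mesh.nearest_node(mid)
            sums = np.zeros(mesh.n_nodes)
            counts = np.zeros(mesh.n_nodes)
            np.add.at(sums, host, pair_rvi)
            np.add.at(counts, host, 1.0)
            got = counts > 0
            values[got] = sums[got] / counts[got]
        return RVIMap(values=values, site_kind="mesh_node", positions=mesh.nodes,
                      config=config, beat=markers.beat)

    n = grid.n_electrodes
    values = np.full(n, np.nan)
    if len(pairs):
        i = pairs[:, 0]
        if config.method == "average":
            sums = np.zeros(n)
            counts = np.zeros(n)
            np.add.at(sums, i, pair_rvi)
            np.add.at(counts, i, 1.0)
            got = counts > 0
            values[got] = sums[got] / counts[got]
        else:  # minimum
            mins = np.full(n, np.inf)
            np.minimum.at(mins, i, pair_rvi)
            got = np.isfinite(mins)
            values[got] = mins[got]
    return RVIMap(values=values, site_kind="electrode", positions=grid.electrodes,
                  config=config, beat=markers.beat)


class VulnerableRegion(NamedTuple):
    size: float  # mm^2 (NaN if no site areas are available)
    lowest: float  # ms (NaN if no value is defined)
    count: int  # number of sub-threshold sites


def quantify_vulnerable_region(rvimap: RVIMap,
                               mesh: LabeledMesh | None = None,
                               grid: RecordingGrid | None = None,
                               threshold: float | None = None) -> VulnerableRegion:
    """Size of the region with RVI strictly below ``threshold``, and lowest RVI.

    Node-indexed maps use the mesh's nodal areas.  Electrode-indexed maps use
    the host node's area when both grid and mesh are given; otherwise only the
    sub-threshold electrode count is meaningful and ``size`` is NaN.
    """
    if threshold is None:
        threshold = rvimap.config.vulnerability_threshold
    v = rvimap.values
    defined = ~np.isnan(v)
    lowest = float(np.nanmin(v)) if defined.any() else float("nan")
    below = defined & (v < threshold)
    count = int(below.sum())
    if rvimap.site_kind == "mesh_node":
        if mesh is None:
            raise ValueError("node-indexed map needs its mesh to compute areas")
        size = float(mesh.node_area[below].sum())
    elif mesh is not None and grid is not None and (grid.host_node >= 0).all():
        size = float(mesh.node_area[grid.host_node[below]].sum())
    else:
        size = float("nan") if count else 0.0
    return VulnerableRegion(size=size, lowest=lowest, count=count)


def sweep(markers: MarkerMap, grid: RecordingGrid,
          methods: Iterable[str] = METHODS,
          radii: Iterable[float] = (4.0, 8.0, 16.0),
          mesh: LabeledMesh | None = None,
          threshold: float = VULNERABILITY_THRESHOLD_MS) -> pd.DataFrame:
    """Vulnerable-region size and lowest RVI over a method x radius grid.

    One row per (method, radius), deterministically ordered.
    """
    rows = []
    for method in methods:
        for r in sorted(radii):
            cfg = RVIConfig(radius=r, method=method, vulnerability_threshold=threshold)
            m = build_map(markers, grid, cfg, mesh=mesh)
            q = quantify_vulnerable_region(m, mesh=mesh, grid=grid)
            rows.append({"method": method, "radius_mm": r,
                         "region_size_mm2": q.size, "lowest_rvi_ms": q.lowest,
                         "n_sites_below": q.count})
    return pd.DataFrame(rows)
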