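"""Idealized infarct geometry and recording-electrode (catheter) layouts.

The tissue model is a regular quadrilateral sheet carrying a per-node region
label: healthy myocardium (MYO), the electrically remodelled border zone (BZ)
rimming the infarct, and the necrotic, non-conducting scar (SCAR).  The scar
consists of two circular segments separated by a straight conducting channel
(the "isthmus") of BZ tissue — the archetypal substrate of scar-related
ventricular tachycardia.

Recording grids mimic clinical electroanatomic mapping hardware: a dense
node-per-electrode grid, a linear decapolar catheter with alternating
intra-pair/inter-pair spacing, a fan of such catheters, and random clusters of
points emulating roving multipolar-catheter acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MYO",
    "BZ",
    "SCAR",
    "REGION_NAMES",
    "InfarctSpec",
    "LabeledMesh",
    "RecordingGrid",
    "build_idealized_infarct_sheet",
    "high_density_grid",
    "place_decapolar",
    "place_fan",
    "place_multipolar_random",
    "DECAPOLAR_2_8_2",
]

MYO, BZ, SCAR = 0, 1, 2
REGION_NAMES = {MYO: "MYO", BZ: "BZ", SCAR: "SCAR"}

#: Decapolar catheter gap sequence: 10 electrodes, bipolar pairs 2 mm apart,
#: 8 mm between consecutive pairs ("2-8-2 mm spacing").
DECAPOLAR_2_8_2: tuple[float, ...] = (2.0, 8.0, 2.0, 8.0, 2.0, 8.0, 2.0, 8.0, 2.0)


@dataclass(frozen=True)
class InfarctSpec:
    """Parameters of the idealized two-scar-segment infarct sheet (mm)."""

    sheet_size: tuple[float, float] = (40.0, 40.0)
    resolution: float = 0.2
    center: tuple[float, float] | None = None
    scar_radius: float = 15.0
    bz_radius: float = 15.5
    isthmus_width: float = 4.0
    #: unit direction of the conducting channel through the scar (vertical by
    #: default, i.e. the channel runs bottom-to-top between the two segments).
    isthmus_axis: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.bz_radius < self.scar_radius:
            raise ValueError("bz_radius must be >= scar_radius")
        if self.isthmus_width < 0:
            raise ValueError("isthmus_width must be non-negative")
        if self.isthmus_width > 2 * self.scar_radius:
            raise ValueError("isthmus_width exceeds the scar diameter: no scar remains")
        cx, cy = self.effective_center
        w, h = self.sheet_size
        r = self.bz_radius
        if cx - r < -1e-9 or cy - r < -1e-9 or cx + r > w + 1e-9 or cy + r > h + 1e-9:
            raise ValueError("sheet does not contain the border-zone disc")
        n = math.hypot(*self.isthmus_axis)
        if n == 0:
            raise ValueError("isthmus_axis must be a non-zero direction")

    @property
    def effective_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return (self.sheet_size[0] / 2.0, self.sheet_size[1] / 2.0)

    @property
    def axis_unit(self) -> np.ndarray:
        a = np.asarray(self.isthmus_axis, dtype=float)
        return a / np.linalg.norm(a)


@dataclass
class LabeledMesh:
    """Regular quadrilateral sheet mesh with per-node region labels.

    ``nodes`` are (N, 2) coordinates in mm, ``elements`` (M, 4) node indices,
    ``region`` an (N,) integer array in {MYO, BZ, SCAR} and ``node_area`` the
    area share associated with each node (interior nodes own one full cell,
    edge/corner nodes the clipped fraction, so areas sum to the sheet area).
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    node_area: np.ndarray
    resolution: float
    shape: tuple[int, int]  # (n_rows, n_cols) of the node lattice
    spec: InfarctSpec | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.nodes.min(axis=0), self.nodes.max(axis=0)

    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.nodes)
        return self._tree

    def nodes_in_region(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.region == label)

    def nearest_node(self, points: np.ndarray) -> np.ndarray:
        """Nearest mesh node per query point; ties broken by lowest index."""
        return _nearest_with_tiebreak(self.kdtree(), self.nodes, np.atleast_2d(points))

    def isthmus_nodes(self) -> np.ndarray:
        """BZ nodes inside the conducting channel through the scar."""
        if self.spec is None:
            raise ValueError("mesh carries no InfarctSpec; isthmus is undefined")
        s = self.spec
        c = np.asarray(s.effective_center)
        d = self.nodes - c
        r = np.linalg.norm(d, axis=1)
        perp = np.abs(d @ _perp(s.axis_unit))
        inside = (r <= s.scar_radius) & (perp < s.isthmus_width / 2.0)
        return np.flatnonzero(inside & (self.region == BZ))

    def total_area(self) -> float:
        return float(self.node_area.sum())


def _perp(axis: np.ndarray) -> np.ndarray:
    return np.array([-axis[1], axis[0]])


def _nearest_with_tiebreak(tree: cKDTree, nodes: np.ndarray, pts: np.ndarray) -> np.ndarray:
    d, idx = tree.query(pts)
    out = np.asarray(idx, dtype=int).copy()
    for k, (p, dk) in enumerate(zip(pts, np.atleast_1d(d))):
        cands = tree.query_ball_point(p, dk + 1e-9)
        if len(cands) > 1:
            out[k] = min(cands)
    return out


def build_idealized_infarct_sheet(spec: InfarctSpec = InfarctSpec()) -> LabeledMesh:
    """Build the labeled sheet mesh for an idealized two-segment infarct.

    The scar is the disc of ``scar_radius`` around the center minus an open
    straight band of width ``isthmus_width`` through the center along
    ``isthmus_axis``.  All remaining tissue within ``bz_radius`` (the channel
    interior plus the thin rim outside the scar) is border zone; everything
    else is healthy myocardium.
    """
    w, h = spec.sheet_size
    res = spec.resolution
    nx, ny = w / res, h / res
    if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
        raise ValueError("resolution must divide the sheet size exactly")
    nx, ny = int(round(nx)), int(round(ny))

    xs = np.linspace(0.0, w, nx + 1)
    ys = np.linspace(0.0, h, ny + 1)
    X, Y = np.meshgrid(xs, ys)  # row-major: index = iy * (nx + 1) + ix
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    # quadrilateral connectivity (counter-clockwise)
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
    n0 = (iy * (nx + 1) + ix).ravel()
    elements = np.column_stack([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])

    c = np.asarray(spec.effective_center)
    d = nodes - c
    r = np.linalg.norm(d, axis=1)
    perp = np.abs(d @ _perp(spec.axis_unit))
    in_channel = perp < spec.isthmus_width / 2.0
    scar = (r <= spec.scar_radius + 1e-12) & ~in_channel
    bz = ~scar & (r <= spec.bz_radius + 1e-12)
    region = np.full(nodes.shape[0], MYO, dtype=np.int8)
    region[bz] = BZ
    region[scar] = SCAR

    # nodal area: full cell interior, clipped share on edges/corners
    wx = np.full(nx + 1, res)
    wx[[0, -1]] = res / 2.0
    wy = np.full(ny + 1, res)
    wy[[0, -1]] = res / 2.0
    node_area = np.outer(wy, wx).ravel()

    return LabeledMesh(
        nodes=nodes,
        elements=elements,
        region=region,
        node_area=node_area,
        resolution=res,
        shape=(ny + 1, nx + 1),
        spec=spec,
    )


@dataclass
class RecordingGrid:
    """Electrode positions attached to their nearest host mesh nodes.

    ``host_node`` is -1 for free-floating grids built from bare point sets
    (e.g. imported clinical marker tables) that carry no mesh.
    """

    electrodes: np.ndarray
    host_node: np.ndarray
    kind: str
    seed: int | None = None
    cluster_id: np.ndarray | None = None
    cluster_centers: np.ndarray | None = None  # node index of each cluster center
    host_region: np.ndarray | None = None

    @property
    def n_electrodes(self) -> int:
        return self.electrodes.shape[0]

    @property
    def on_scar(self) -> np.ndarray:
        """Electrodes sitting on scar nodes (these yield no AT/RT markers)."""
        if self.host_region is None:
            return np.zeros(self.n_electrodes, dtype=bool)
        return self.host_region == SCAR

    @classmethod
    def from_points(cls, points: np.ndarray, kind: str = "imported") -> "RecordingGrid":
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return cls(
            electrodes=points,
            host_node=np.full(points.shape[0], -1, dtype=int),
            kind=kind,
        )


def _attach(mesh: LabeledMesh, points: np.ndarray, kind: str,
            seed: int | None = None, cluster_id: np.ndarray | None = None) -> RecordingGrid:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    lo, hi = mesh.bounding_box
    outside = np.flatnonzero(
        (points < lo - 1e-9).any(axis=1) | (points > hi + 1e-9).any(axis=1)
    )
    if outside.size:
        raise ValueError(
            f"electrode {int(outside[0])} at {points[outside[0]]} falls outside "
            f"the mesh bounding box"
        )
    host = mesh.nearest_node(points)
    return RecordingGrid(
        electrodes=points,
        host_node=host,
        kind=kind,
        seed=seed,
        cluster_id=cluster_id,
        host_region=mesh.region[host],
    )


def high_density_grid(mesh: LabeledMesh, include_scar: bool = False) -> RecordingGrid:
    """Every (non-scar by default) mesh node as a recording electrode."""
    idx = np.arange(mesh.n_nodes) if include_scar else np.flatnonzero(mesh.region != SCAR)
    return RecordingGrid(
        electrodes=mesh.nodes[idx],
        host_node=idx,
        kind="high_density",
        host_region=mesh.region[idx],
    )


def _polyline_positions(origin: np.ndarray, direction: np.ndarray,
                        spacing_pattern: Sequence[float]) -> np.ndarray:
    direction = np.asarray(direction, dtype=float)
    n = np.linalg.norm(direction)
    if n == 0:
        raise ValueError("direction must be non-zero")
    direction = direction / n
    pattern = np.asarray(spacing_pattern, dtype=float)
    if (pattern <= 0).any():
        raise ValueError("spacing pattern entries must be positive")
    dists = np.concatenate([[0.0], np.cumsum(pattern)])
    return np.asarray(origin, dtype=float)[None, :] + dists[:, None] * direction[None, :]


def place_decapolar(mesh: LabeledMesh, origin, direction,
                    spacing_pattern: Sequence[float] = DECAPOLAR_2_8_2) -> RecordingGrid:
    """Linear multi-electrode catheter; default is the 10-pole 2-8-2 mm layout."""
    pts = _polyline_positions(np.asarray(origin, float), direction, spacing_pattern)
    return _attach(mesh, pts, kind="decapolar")


def place_fan(mesh: LabeledMesh, origin, arm_angles_deg: Sequence[float],
              spacing_pattern: Sequence[float] = DECAPOLAR_2_8_2) -> RecordingGrid:
    """Fan of linear catheters sharing an origin, one arm per angle (degrees)."""
    angles = np.asarray(arm_angles_deg, dtype=float)
    if np.unique(angles).size != angles.size:
        raise ValueError("arm angles must be distinct")
    arms = []
    for a in angles:
        d = np.array([math.cos(math.radians(a)), math.sin(math.radians(a))])
        arms.append(_polyline_positions(np.asarray(origin, float), d, spacing_pattern))
    pts = np.vstack(arms)
    grid = _attach(mesh, pts, kind="fan")
    n_per_arm = len(spacing_pattern) + 1
    grid.cluster_id = np.repeat(np.arange(angles.size), n_per_arm)
    return grid


def place_multipolar_random(mesh: LabeledMesh, n_clusters: int = 50,
                            cluster_radius: float = 1.5,
                            node_fraction: float = 0.05,
                            seed: int | None = 0) -> RecordingGrid:
    """Random clusters of mesh nodes emulating roving multipolar acquisition.

    ``n_clusters`` cluster centers are drawn uniformly without replacement from
    the mesh nodes; each cluster is a uniform sample of
    ``ceil(node_fraction * |ball|)`` nodes within ``cluster_radius`` of its
    center.  Reproducible for a fixed seed.
    """
    if not 0 < node_fraction <= 1:
        raise ValueError("node_fraction must be in (0, 1]")
    if n_clusters > mesh.n_nodes:
        raise ValueError("n_clusters exceeds the number of mesh nodes")
    rng = np.random.default_rng(seed)
    centers = rng.choice(mesh.n_nodes, size=n_clusters, replace=False)
    tree = mesh.kdtree()
    picked: list[np.ndarray] = []
    cluster_of: list[np.ndarray] = []
    for ci, center in enumerate(centers):
        ball = np.sort(np.asarray(tree.query_ball_point(mesh.nodes[center], cluster_radius)))
        k = int(math.ceil(node_fraction * ball.size))
        sel = rng.choice(ball, size=k, replace=False)
        picked.append(sel)
        cluster_of.append(np.full(k, ci))
    idx = np.concatenate(picked)
    return RecordingGrid(
        electrodes=mesh.nodes[idx],
        host_node=idx,
        kind="multipolar_random",
        seed=seed,
        cluster_id=np.concatenate(cluster_of),
        cluster_centers=centers,
        host_region=mesh.region[idx],
    )
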