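"""Analytic AT/RT field generators: closed-form oracles for the RVI core.

These fields encode the wavefront-waveback geometry of re-entry analytically,
without running the tissue simulator:

* ``planar_wave_field`` — a uniform plane wave, AT = s / CV along the
  propagation direction and RT = AT + APD.  Every pairwise RVI is then
  APD - (AT(j) - AT(i)), so the minimum-interpolation map converges to
  APD - R / CV at interior sites.
* ``line_of_block_field`` — a plane wave that is blocked along a straight
  segment: sites in the "shadow" downstream of the segment activate late, by a
  fixed detour time.  Cross-block pairs then have RVI = APD - detour -
  gap / CV, so a detour exceeding APD creates a strip of negative RVI just
  proximal to the line — the analytic stand-in for a vulnerable region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RecordingGrid
from .markers import MarkerMap

__all__ = ["FieldSpec", "planar_wave_field", "line_of_block_field", "BlockFieldOracle"]


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of an analytic marker field.

    cv is the conduction velocity in mm/ms, apd the action potential duration
    in ms.  ``rt_gradient`` (ms/mm) adds a linear APD drift along the
    propagation direction.  ``block_line`` is a segment ((x0, y0), (x1, y1))
    and ``at_offset_across_block`` the extra detour time (ms) picked up by
    sites downstream of it.
    """

    kind: str = "planar_wave"
    cv: float = 0.5
    apd: float = 200.0
    direction: tuple[float, float] = (0.0, 1.0)
    rt_gradient: float = 0.0
    block_line: tuple[tuple[float, float], tuple[float, float]] | None = None
    at_offset_across_block: float = 0.0

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.apd < 0:
            raise ValueError("apd must be non-negative")

    @property
    def unit_direction(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        return d / np.linalg.norm(d)


def planar_wave_field(spec: FieldSpec, grid: RecordingGrid) -> MarkerMap:
    """Uniform plane wave: AT = s / cv, RT = AT + apd (+ optional drift)."""
    s = grid.electrodes @ spec.unit_direction
    at = s / spec.cv
    rt = at + spec.apd + spec.rt_gradient * s
    return MarkerMap(beat="SYN_PLANAR", at=at, rt=rt,
                     meta={"field": "planar_wave", "cv": spec.cv, "apd": spec.apd})


def _shadow_mask(spec: FieldSpec, points: np.ndarray) -> np.ndarray:
    """Sites downstream of the block segment (late-activating side)."""
    (p0, p1) = spec.block_line
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = spec.unit_direction
    seg = p1 - p0
    lat = seg - (seg @ d) * d  # lateral extent of the segment
    lat_len = np.linalg.norm(lat)
    if lat_len == 0:
        raise ValueError("block line must have lateral extent across the wave direction")
    lat_u = lat / lat_len
    rel = points - p0
    # signed distance past the (possibly oblique) segment along the wave
    past = rel @ d - (seg @ d) * np.clip((rel @ lat_u) / lat_len, 0, 1)
    lateral = rel @ lat_u
    return (past > 0) & (lateral >= 0) & (lateral <= lat_len)


@dataclass
class BlockFieldOracle:
    """Analytic companion of a line-of-block field."""

    spec: FieldSpec
    shadow: np.ndarray  # per-electrode: downstream of the block line

    def negative_strip(self, grid: RecordingGrid, radius: float,
                       threshold: float = 0.0) -> np.ndarray:
        """Electrodes predicted to be sub-threshold on the minimum-method map.

        A proximal site is in the strip iff some shadow site lies within the
        search radius and the best cross-block pair can push its RVI below the
        threshold: apd - detour - gap/cv < threshold with gap up to the radius.
        """
        spec = self.spec
        if spec.apd - spec.at_offset_across_block - radius / spec.cv >= threshold:
            return np.zeros(grid.n_electrodes, dtype=bool)
        prox = ~self.shadow
        # distance from each proximal electrode to the nearest shadow electrode
        from scipy.spatial import cKDTree

        shadow_pts = grid.electrodes[self.shadow]
        if shadow_pts.shape[0] == 0:
            return np.zeros(grid.n_electrodes, dtype=bool)
        dist, _ = cKDTree(shadow_pts).query(grid.electrodes)
        return prox & (dist <= radius)


def line_of_block_field(spec: FieldSpec, grid: RecordingGrid
                        ) -> tuple[MarkerMap, BlockFieldOracle]:
    """Plane wave with a straight line of block.

    Sites downstream of the block segment (its "shadow") activate late by
    ``at_offset_across_block`` — the time the wavefront needs to detour around
    the line.  RT = AT + apd everywhere, so adjacent cross-block pairs have
    RVI ~= apd - at_offset; an offset exceeding apd yields a negative-RVI
    strip just proximal to the line, returned analytically in the oracle.
    """
    if spec.block_line is None:
        raise ValueError("line_of_block_field requires spec.block_line")
    pts = grid.electrodes
    # the segment must at least overlap the grid laterally (across the wave
    # direction); a grid entirely proximal or distal of the line is legitimate
    d = spec.unit_direction
    lat_u = np.array([-d[1], d[0]])
    margin = max(2.0, 0.05 * np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    seg_lat = np.asarray(spec.block_line, dtype=float) @ lat_u
    grid_lat = pts @ lat_u
    if seg_lat.max() < grid_lat.min() - margin or seg_lat.min() > grid_lat.max() + margin:
        raise ValueError("block line must lie inside the grid extent laterally")
    s = pts @ spec.unit_direction
    at = s / spec.cv
    shadow = _shadow_mask(spec, pts)
    at = at + np.where(shadow, spec.at_offset_across_block, 0.0)
    rt = at + spec.apd + spec.rt_gradient * s
    mm = MarkerMap(beat="SYN_BLOCK", at=at, rt=rt,
                   meta={"field": "line_of_block", "cv": spec.cv, "apd": spec.apd,
                         "at_offset": spec.at_offset_across_block})
    return mm, BlockFieldOracle(spec=spec, shadow=shadow)
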