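"""Activation/repolarization marker extraction and marker-map utilities.

Activation time (AT) is the first upward crossing of -20 mV of the
transmembrane voltage within a beat window; repolarization time (RT) the first
downward crossing of -70 mV after that activation.  Both are located by linear
interpolation between samples.  APD = RT - AT.

Marker maps are beat-relative: AT/RT are measured from the owning beat's
stimulus onset (``t0``); absolute times are ``t0 + value``.  Undefined entries
(scar electrodes, sites without capture) are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "AT_THRESHOLD_MV",
    "RT_THRESHOLD_MV",
    "extract_markers",
    "add_marker_noise",
    "restitution_difference_maps",
]

AT_THRESHOLD_MV = -20.0
RT_THRESHOLD_MV = -70.0


@dataclass
class MarkerMap:
    """Per-electrode AT and RT (ms, beat-relative) for one named beat."""

    beat: str
    at: np.ndarray
    rt: np.ndarray
    t0: float = 0.0  # stimulus onset of this beat (absolute ms)
    at_threshold: float = AT_THRESHOLD_MV
    rt_threshold: float = RT_THRESHOLD_MV
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.at = np.asarray(self.at, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        if self.at.shape != self.rt.shape:
            raise ValueError("AT and RT arrays must have the same shape")

    @property
    def n_sites(self) -> int:
        return self.at.size

    @property
    def apd(self) -> np.ndarray:
        """Action potential duration RT - AT (NaN where either is undefined)."""
        return self.rt - self.at

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.at)

    @property
    def at_absolute(self) -> np.ndarray:
        return self.at + self.t0

    @property
    def rt_absolute(self) -> np.ndarray:
        return self.rt + self.t0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"electrode_id": np.arange(self.n_sites), "beat": self.beat,
             "AT": self.at, "RT": self.rt}
        )


def _first_crossing(t: np.ndarray, v: np.ndarray, threshold: float,
                    rising: bool) -> float:
    """Time of the first linear-interpolated threshold crossing, or NaN."""
    if rising:
        hit = (v[:-1] < threshold) & (v[1:] >= threshold)
    else:
        hit = (v[:-1] > threshold) & (v[1:] <= threshold)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return float("nan")
    k = idx[0]
    frac = (threshold - v[k]) / (v[k + 1] - v[k])
    return float(t[k] + frac * (t[k + 1] - t[k]))


def extract_markers(times: np.ndarray, traces: np.ndarray,
                    windows: list[tuple[float, float]],
                    beat_labels: list[str] | None = None,
                    at_threshold: float = AT_THRESHOLD_MV,
                    rt_threshold: float = RT_THRESHOLD_MV) -> list[MarkerMap]:
    """Extract per-beat AT/RT from voltage traces.

    Parameters
    ----------
    times : (S,) uniform sample times (ms).
    traces : (S, E) transmembrane voltage per electrode (mV).
    windows : stimulus-aligned ``(onset, end)`` intervals, ordered and
        non-overlapping at onset.  AT is searched within its window; RT is
        searched forward from AT (it may fall past the window end, as late
        repolarization of a premature beat does).
    """
    times = np.asarray(times, dtype=float)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] != times.size:
        raise ValueError("traces must be sampled at `times` along axis 0")
    if not np.isfinite(traces).all():
        raise ValueError("non-finite voltage samples in trace")
    onsets = [w[0] for w in windows]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("windows must be ordered by onset")
    if beat_labels is None:
        beat_labels = [f"S1_{k + 1}" for k in range(len(windows))]

    n_e = traces.shape[1]
    maps: list[MarkerMap] = []
    for (w0, w1), label in zip(windows, beat_labels):
        at = np.full(n_e, np.nan)
        rt = np.full(n_e, np.nan)
        sel = (times >= w0) & (times < w1)
        for e in range(n_e):
            a = _first_crossing(times[sel], traces[sel, e], at_threshold, rising=True)
            if np.isnan(a):
                continue
            after = times >= a
            r = _first_crossing(times[after], traces[after, e], rt_threshold, rising=False)
            at[e] = a - w0
            rt[e] = r - w0 if not np.isnan(r) else np.nan
        maps.append(MarkerMap(beat=label, at=at, rt=rt, t0=w0,
                              at_threshold=at_threshold, rt_threshold=rt_threshold))
    return maps


def add_marker_noise(markers: MarkerMap, sd_at: float = 5.0, sd_rt: float = 5.0,
                     seed: int | None = 0) -> MarkerMap:
    """Add independent zero-mean Gaussian noise to defined AT and RT entries."""
    if sd_at < 0 or sd_rt < 0:
        raise ValueError("noise standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    at = markers.at.copy()
    rt = markers.rt.copy()
    # draw per-site so that defined/undefined patterns do not shift the stream
    noise_at = rng.normal(0.0, sd_at, size=at.shape) if sd_at > 0 else 0.0
    noise_rt = rng.normal(0.0, sd_rt, size=rt.shape) if sd_rt > 0 else 0.0
    if sd_at > 0:
        at = np.where(np.isnan(at), at, at + noise_at)
    if sd_rt > 0:
        rt = np.where(np.isnan(rt), rt, rt + noise_rt)
    out = replace(markers, at=at, rt=rt)
    out.meta = dict(markers.meta, noise_sd_at=sd_at, noise_sd_rt=sd_rt, noise_seed=seed)
    return out


def restitution_difference_maps(s1: MarkerMap, s2: MarkerMap
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Beat-relative activation and APD differences between two beats.

    Returns ``(delta_at, delta_apd)`` with ``delta_at = AT_s2 - AT_s1`` (each
    measured from its own stimulus onset) and ``delta_apd = APD_s2 - APD_s1``.
    Undefined entries propagate as NaN.
    """
    if s1.n_sites != s2.n_sites:
        raise ValueError("marker maps cover different electrode sets")
    return s2.at - s1.at, s2.apd - s1.apd
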