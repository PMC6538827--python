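"""Monodomain reaction-diffusion simulation on the labeled sheet.

The tissue is stepped with an explicit operator-split scheme: a 5-point
finite-difference Laplacian with harmonic-mean face conductivities (zero-flux
at sheet edges and at scar interfaces, so the scar is purely an obstacle) plus
a two-variable phenomenological ionic model of the Mitchell-Schaeffer family.

The ionic model evolves a normalized voltage u in [0, 1] and a recovery gate h:

    du/dt = h u^2 (1 - u) / tau_in - u / tau_out + J_stim + diffusion
    dh/dt = (1 - h) / tau_open   if u < u_gate
          = -h / tau_close       otherwise

It has an explicit action-potential-duration (APD) restitution — APD grows
monotonically with the diastolic interval and scales nearly linearly with
``tau_close`` — which makes it calibratable to region-specific APD targets.
Border-zone ionic remodelling (down-regulated repolarizing currents) is
emulated by a BZ APD-prolongation factor on ``tau_close``; structural
remodelling by a BZ conductivity scaling.

Physical voltage is mapped linearly: Vm = v_rest + u (v_peak - v_rest).
Activation and repolarization times are captured on the fly at every node
(first -20 mV upstroke per beat window; first -70 mV downstroke after it,
allowed to spill past the window end), so full-field marker maps come out of a
run without storing full-field traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import BZ, MYO, SCAR, LabeledMesh, RecordingGrid
from .markers import AT_THRESHOLD_MV, RT_THRESHOLD_MV, MarkerMap

__all__ = [
    "IonicParams",
    "TissueParams",
    "PacingProtocol",
    "SimResult",
    "run_monodomain",
    "build_cable_mesh",
    "run_single_cell",
    "apd_restitution",
    "calibrate_ionic_params",
    "make_bz_variant",
    "conduction_velocity",
]


@dataclass(frozen=True)
class IonicParams:
    """Two-variable phenomenological membrane model parameters (ms / mV)."""

    tau_in: float = 0.2
    tau_out: float = 6.0
    tau_open: float = 80.0
    tau_close: float = 70.84
    u_gate: float = 0.13
    v_rest: float = -80.0
    v_peak: float = 20.0

    def __post_init__(self) -> None:
        for name in ("tau_in", "tau_out", "tau_open", "tau_close"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.v_peak <= self.v_rest:
            raise ValueError("v_peak must exceed v_rest")

    def u_of_v(self, v_mv: float) -> float:
        return (v_mv - self.v_rest) / (self.v_peak - self.v_rest)

    def v_of_u(self, u: np.ndarray) -> np.ndarray:
        return self.v_rest + u * (self.v_peak - self.v_rest)


@dataclass(frozen=True)
class TissueParams:
    """Bulk tissue parameters.

    sigma: bulk conductivity (S/m, isotropic); beta: surface-to-volume ratio
    (1/um); cm: membrane capacitance (uF/cm^2).  The effective voltage
    diffusivity is D = sigma / (beta cm), which in mm^2/ms is
    0.1 * sigma / (beta * cm) for these units.
    """

    sigma: float = 0.068
    beta: float = 0.14
    cm: float = 1.0
    ionic_myo: IonicParams = IonicParams()
    bz_apd_prolongation: float = 1.725
    bz_refractory_prolongation: float = 4.0
    bz_sigma_scaling: float = 1.0
    dt: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.beta <= 0 or self.cm <= 0:
            raise ValueError("beta and cm must be positive")
        if (self.bz_apd_prolongation <= 0 or self.bz_sigma_scaling <= 0
                or self.bz_refractory_prolongation <= 0):
            raise ValueError("BZ scaling factors must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def ionic_bz(self) -> IonicParams:
        return replace(
            self.ionic_myo,
            tau_close=self.ionic_myo.tau_close * self.bz_apd_prolongation,
            tau_open=self.ionic_myo.tau_open * self.bz_refractory_prolongation,
        )

    @property
    def diffusivity(self) -> float:
        """Voltage diffusivity in mm^2/ms for healthy tissue."""
        return 0.1 * self.sigma / (self.beta * self.cm)


def make_bz_variant(params: TissueParams, variant: str) -> TissueParams:
    """Border-zone electrophysiology variants.

    ``long_apd``   — ionic remodelling only (BZ APD and post-repolarization
                     refractoriness prolonged, conduction normal);
    ``slow_cv``    — structural remodelling only (BZ conductivity cut by 90%,
                     BZ APD equal to myocardium);
    ``homogeneous``— BZ identical to healthy myocardium.
    """
    if variant == "long_apd":
        return replace(params, bz_sigma_scaling=1.0)
    if variant == "slow_cv":
        return replace(params, bz_apd_prolongation=1.0,
                       bz_refractory_prolongation=1.0, bz_sigma_scaling=0.1)
    if variant == "homogeneous":
        return replace(params, bz_apd_prolongation=1.0,
                       bz_refractory_prolongation=1.0, bz_sigma_scaling=1.0)
    raise ValueError(f"unknown BZ variant {variant!r}")


@dataclass(frozen=True)
class PacingProtocol:
    """S1-S2 stimulation: ``n_s1`` beats at ``bcl`` ms, then an optional
    premature S2 at coupling interval ``s2_coupling`` after the last S1.

    The stimulus is a transmembrane current injected for ``stim_duration`` ms
    into a strip of nodes ``stim_depth`` mm deep along the ``stim_edge`` of the
    sheet (the lowermost edge by default); ``stim_nodes`` overrides the strip
    with an explicit node set.
    """

    n_s1: int = 3
    bcl: float = 500.0
    s2_coupling: float | None = 220.0
    stim_depth: float = 2.0
    stim_duration: float = 2.0
    stim_amplitude: float = 0.6  # d(u)/dt units, 1/ms
    stim_edge: str = "ymin"
    stim_nodes: np.ndarray | None = None
    total_time: float | None = None

    def __post_init__(self) -> None:
        if self.n_s1 < 1:
            raise ValueError("need at least one S1 beat")
        if self.s2_coupling is not None and not 0 < self.s2_coupling < self.bcl:
            raise ValueError("S2 coupling interval must lie in (0, BCL)")

    @property
    def stim_times(self) -> list[float]:
        times = [k * self.bcl for k in range(self.n_s1)]
        if self.s2_coupling is not None:
            times.append(times[-1] + self.s2_coupling)
        return times

    @property
    def beat_labels(self) -> list[str]:
        labels = [f"S1_{k + 1}" for k in range(self.n_s1)]
        if self.s2_coupling is not None:
            labels.append("S2")
        return labels

    @property
    def duration(self) -> float:
        if self.total_time is not None:
            return self.total_time
        extra = self.s2_coupling if self.s2_coupling is not None else 0.0
        return self.n_s1 * self.bcl + extra + 800.0

    @property
    def windows(self) -> list[tuple[float, float]]:
        t = self.stim_times
        return [(a, b) for a, b in zip(t, t[1:])] + [(t[-1], self.duration)]

    def stim_mask(self, mesh: LabeledMesh) -> np.ndarray:
        if self.stim_nodes is not None:
            mask = np.zeros(mesh.n_nodes, dtype=bool)
            mask[np.asarray(self.stim_nodes, dtype=int)] = True
        else:
            axis = 1 if self.stim_edge == "ymin" else 0
            lo = mesh.nodes[:, axis].min()
            mask = mesh.nodes[:, axis] <= lo + self.stim_depth + 1e-9
        mask &= mesh.region != SCAR
        if not mask.any():
            raise ValueError("stimulus region is empty (or entirely scar)")
        return mask


@dataclass
class SimResult:
    """Voltage recordings plus full-field, per-beat AT/RT capture.

    ``node_at`` / ``node_rt`` are (n_beats, n_nodes) beat-relative marker
    times (NaN where no crossing occurred, e.g. scar or block).
    """

    times: np.ndarray
    traces: np.ndarray  # (S, E) mV at the recording electrodes
    stim_times: list[float]
    beat_labels: list[str]
    windows: list[tuple[float, float]]
    node_at: np.ndarray
    node_rt: np.ndarray
    params: TissueParams
    protocol: PacingProtocol
    snapshots: dict[float, np.ndarray] = field(default_factory=dict)

    def marker_maps(self, grid: RecordingGrid | None = None) -> list[MarkerMap]:
        """Per-beat marker maps, full-field or restricted to a grid's hosts."""
        maps = []
        for b, (label, (w0, _)) in enumerate(zip(self.beat_labels, self.windows)):
            at, rt = self.node_at[b], self.node_rt[b]
            if grid is not None:
                if (grid.host_node < 0).any():
                    raise ValueError("grid has electrodes without host mesh nodes")
                at, rt = at[grid.host_node], rt[grid.host_node]
            maps.append(MarkerMap(beat=label, at=at.copy(), rt=rt.copy(), t0=w0))
        return maps

    def marker_map(self, beat: str, grid: RecordingGrid | None = None) -> MarkerMap:
        for m in self.marker_maps(grid):
            if m.beat == beat:
                return m
        raise KeyError(beat)


def _face_weights(mesh: LabeledMesh, params: TissueParams) -> tuple[np.ndarray, ...]:
    """Per-face diffusion weights (1/ms) on the node lattice.

    The weight between adjacent nodes is the harmonic mean of their nodal
    diffusivities divided by dx^2; scar nodes have zero diffusivity, so faces
    touching scar carry no flux (the no-flux scar boundary condition).
    """
    nr, nc = mesh.shape
    sig = np.full(mesh.n_nodes, params.sigma)
    sig[mesh.region == BZ] = params.sigma * params.bz_sigma_scaling
    sig[mesh.region == SCAR] = 0.0
    d = (0.1 * sig / (params.beta * params.cm)).reshape(nr, nc)
    dx2 = mesh.resolution ** 2

    def harm(a, b):
        s = a + b
        out = np.zeros_like(s)
        nz = s > 0
        out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
        return out / dx2

    w_e = harm(d[:, :-1], d[:, 1:])  # (nr, nc-1) between (i,j) and (i,j+1)
    w_s = harm(d[:-1, :], d[1:, :])  # (nr-1, nc) between (i,j) and (i+1,j)
    return w_e, w_s


def _check_stability(mesh: LabeledMesh, params: TissueParams) -> None:
    d_max = params.diffusivity * max(1.0, params.bz_sigma_scaling)
    n_dims = 2 if min(mesh.shape) > 1 else 1
    bound = mesh.resolution ** 2 / (2.0 * n_dims * d_max) if d_max > 0 else math.inf
    if params.dt > bound:
        raise ValueError(
            f"dt={params.dt} ms violates the explicit stability bound "
            f"{bound:.4f} ms for dx={mesh.resolution} mm"
        )


def run_monodomain(mesh: LabeledMesh, params: TissueParams,
                   protocol: PacingProtocol,
                   grid: RecordingGrid | None = None,
                   snapshot_times: tuple[float, ...] = (),
                   trace_interval: float = 1.0,
                   u0: np.ndarray | None = None,
                   include_reaction: bool = True) -> SimResult:
    """Explicit operator-split monodomain run with online marker capture.

    ``u0`` (normalized units) and ``include_reaction=False`` are numerical
    verification hooks: an initial condition with the membrane switched off
    exposes the bare diffusion operator (whose zero-flux boundaries conserve
    the spatial mean of the voltage).
    """
    _check_stability(mesh, params)
    nr, nc = mesh.shape
    dt = params.dt
    n_steps = int(round(protocol.duration / dt))
    ion_m, ion_b = params.ionic_myo, params.ionic_bz

    region = mesh.region
    scar = (region == SCAR).reshape(nr, nc)
    bz_mask = region == BZ
    tau_close = np.where(bz_mask, ion_b.tau_close, ion_m.tau_close).reshape(nr, nc)
    tau_open = np.where(bz_mask, ion_b.tau_open, ion_m.tau_open).reshape(nr, nc)
    tau_in, tau_out = ion_m.tau_in, ion_m.tau_out
    u_gate = ion_m.u_gate

    w_e, w_s = _face_weights(mesh, params)

    stim = protocol.stim_mask(mesh).reshape(nr, nc)
    stim_times = protocol.stim_times
    windows = protocol.windows
    n_beats = len(windows)

    u = np.zeros((nr, nc)) if u0 is None else np.asarray(u0, float).reshape(nr, nc).copy()
    h = np.ones((nr, nc))

    # marker state
    u_at = ion_m.u_of_v(AT_THRESHOLD_MV)
    u_rt = ion_m.u_of_v(RT_THRESHOLD_MV)
    at_abs = np.full((n_beats, nr, nc), np.nan)
    rt_abs = np.full((n_beats, nr, nc), np.nan)

    # trace sampling
    sample_every = max(1, int(round(trace_interval / dt)))
    n_samp = n_steps // sample_every + 1
    times = np.empty(n_samp)
    host = None
    if grid is not None:
        if (grid.host_node < 0).any():
            raise ValueError("grid has electrodes without host mesh nodes")
        host = grid.host_node
    traces = np.empty((n_samp, host.size if host is not None else 0))
    snapshots: dict[float, np.ndarray] = {}
    snap_steps = {int(round(t / dt)): t for t in snapshot_times}

    def record(k: int, s: int) -> None:
        times[s] = k * dt
        if host is not None:
            traces[s] = ion_m.v_of_u(u.ravel()[host])

    record(0, 0)
    s_idx = 1
    beat = 0
    du = np.empty_like(u)

    for k in range(n_steps):
        t = k * dt
        t_new = t + dt
        # advance the beat window
        while beat + 1 < n_beats and t_new > windows[beat + 1][0] + 1e-9:
            beat += 1

        # diffusion (zero-flux edges; scar faces carry zero weight)
        du.fill(0.0)
        du[:, :-1] += w_e * (u[:, 1:] - u[:, :-1])
        du[:, 1:] += w_e * (u[:, :-1] - u[:, 1:])
        if nr > 1:
            du[:-1, :] += w_s * (u[1:, :] - u[:-1, :])
            du[1:, :] += w_s * (u[:-1, :] - u[1:, :])

        # reaction
        if include_reaction:
            du += h * u * u * (1.0 - u) / tau_in - u / tau_out

        # stimulus
        for t0 in stim_times:
            if t0 - 1e-9 <= t < t0 + protocol.stim_duration - 1e-9:
                du += np.where(stim, protocol.stim_amplitude, 0.0)

        u_prev = u.copy()
        u += dt * du
        if include_reaction:
            u[scar] = 0.0
            np.clip(u, -0.2, 1.5, out=u)

        h += dt * np.where(u < u_gate, (1.0 - h) / tau_open, -h / tau_close)
        np.clip(h, 0.0, 1.0, out=h)

        # marker crossings (linear interpolation within the step)
        up = (u_prev < u_at) & (u >= u_at) & np.isnan(at_abs[beat])
        if up.any():
            frac = (u_at - u_prev[up]) / (u[up] - u_prev[up])
            at_abs[beat][up] = t + frac * dt
        down = (u_prev > u_rt) & (u <= u_rt)
        if down.any():
            t_cross = np.full_like(u, np.nan)
            frac = (u_rt - u_prev[down]) / (u[down] - u_prev[down])
            t_cross[down] = t + frac * dt
            remaining = down
            # a downstroke belongs to the current beat if it follows that
            # beat's activation, else to a repolarization still pending from
            # the previous beat (late RT spilling past the window end)
            for b in (beat, beat - 1):
                if b < 0 or not remaining.any():
                    continue
                assign = (remaining & ~np.isnan(at_abs[b])
                          & np.isnan(rt_abs[b]) & (t_cross > at_abs[b]))
                rt_abs[b][assign] = t_cross[assign]
                remaining = remaining & ~assign

        if (k + 1) % sample_every == 0:
            record(k + 1, s_idx)
            s_idx += 1
        if (k + 1) in snap_steps:
            snapshots[snap_steps[k + 1]] = ion_m.v_of_u(u.ravel().copy())
        if (k + 1) % 2000 == 0 and not np.isfinite(u).all():
            raise RuntimeError(f"simulation diverged at t={t_new:.2f} ms")

    if not np.isfinite(u).all():
        raise RuntimeError("simulation diverged at final time")

    # beat-relative marker times
    n_nodes = mesh.n_nodes
    node_at = at_abs.reshape(n_beats, n_nodes).copy()
    node_rt = rt_abs.reshape(n_beats, n_nodes).copy()
    for b, (w0, _) in enumerate(windows):
        node_at[b] -= w0
        node_rt[b] -= w0

    return SimResult(
        times=times[:s_idx], traces=traces[:s_idx], stim_times=stim_times,
        beat_labels=protocol.beat_labels, windows=windows,
        node_at=node_at, node_rt=node_rt, params=params, protocol=protocol,
        snapshots=snapshots,
    )


def build_cable_mesh(length: float = 20.0, resolution: float = 0.2,
                     region_label: int = MYO) -> LabeledMesh:
    """1D strip of tissue (a cable), reusing the sheet machinery with one row."""
    n = int(round(length / resolution))
    if abs(n * resolution - length) > 1e-9:
        raise ValueError("resolution must divide the cable length exactly")
    xs = np.linspace(0.0, length, n + 1)
    nodes = np.column_stack([xs, np.zeros_like(xs)])
    elements = np.column_stack([np.arange(n), np.arange(1, n + 1)])
    area = np.full(n + 1, resolution)
    area[[0, -1]] = resolution / 2.0
    return LabeledMesh(nodes=nodes, elements=elements,
                       region=np.full(n + 1, region_label, dtype=np.int8),
                       node_area=area, resolution=resolution, shape=(1, n + 1))


def run_single_cell(ionic: IonicParams, stim_times: list[float],
                    total_time: float, dt: float = 0.02,
                    stim_duration: float = 2.0,
                    stim_amplitude: float = 0.6) -> tuple[np.ndarray, np.ndarray]:
    """Space-clamped (0D) membrane run; returns (times, Vm)."""
    n_steps = int(round(total_time / dt))
    u, h = 0.0, 1.0
    v = np.empty(n_steps + 1)
    t_arr = np.arange(n_steps + 1) * dt
    v[0] = ionic.v_of_u(np.array(u))
    for k in range(n_steps):
        t = k * dt
        du = h * u * u * (1.0 - u) / ionic.tau_in - u / ionic.tau_out
        for t0 in stim_times:
            if t0 - 1e-9 <= t < t0 + stim_duration - 1e-9:
                du += stim_amplitude
        u += dt * du
        dh = (1.0 - h) / ionic.tau_open if u < ionic.u_gate else -h / ionic.tau_close
        h = min(1.0, max(0.0, h + dt * dh))
        v[k + 1] = ionic.v_of_u(np.array(u))
    return t_arr, v


def apd_restitution(ionic: IonicParams, coupling_intervals: np.ndarray,
                    bcl: float = 500.0, n_s1: int = 3,
                    dt: float = 0.02) -> np.ndarray:
    """Single-cell S2 APD (ms) as a function of the S1-S2 coupling interval."""
    from .markers import extract_markers

    out = []
    for ci in np.atleast_1d(coupling_intervals):
        stim_times = [k * bcl for k in range(n_s1)]
        stim_times.append(stim_times[-1] + float(ci))
        total = stim_times[-1] + 500.0
        t, v = run_single_cell(ionic, stim_times, total, dt=dt)
        windows = [(a, b) for a, b in zip(stim_times, stim_times[1:])]
        windows.append((stim_times[-1], total))
        maps = extract_markers(t, v[:, None], windows)
        out.append(float(maps[-1].apd[0]))
    return np.asarray(out)


def _cable_apd(params: TissueParams, region_label: int, bcl: float,
               n_s1: int, length: float = 20.0) -> float:
    """Steady-state APD at the middle of a paced cable of one tissue type."""
    mesh = build_cable_mesh(length=length, resolution=0.2, region_label=region_label)
    protocol = PacingProtocol(n_s1=n_s1, bcl=bcl, s2_coupling=None,
                              stim_edge="xmin", stim_depth=1.0,
                              total_time=(n_s1 - 1) * bcl + 450.0)
    res = run_monodomain(mesh, params, protocol)
    mid = mesh.n_nodes // 2
    return float(res.node_rt[n_s1 - 1, mid] - res.node_at[n_s1 - 1, mid])


def calibrate_ionic_params(targets: dict[str, float],
                           base: TissueParams | None = None,
                           bcl: float = 500.0, n_s1: int = 3,
                           tol: float = 0.5, max_iter: int = 15) -> TissueParams:
    """Calibrate tau_close so that paced-strip APDs hit region targets.

    ``targets`` maps region names ("myo", "bz") to APD targets in ms at the
    given BCL, measured on a 1D strip (which a plane wave in the sheet reduces
    to).  APD is monotone in tau_close, so a damped proportional fixed-point
    iteration converges in a handful of steps; parameters already within
    ``tol`` of target are returned unchanged.  Deterministic given targets.
    """
    params = base if base is not None else TissueParams()

    def solve(region_label: int, get_tau, set_tau, target: float) -> TissueParams:
        nonlocal params
        tau = get_tau(params)
        apd = _cable_apd(params, region_label, bcl, n_s1)
        lo_tau = hi_tau = None
        for _ in range(max_iter):
            if abs(apd - target) <= tol:
                return params
            if apd < target:
                lo_tau = tau
            else:
                hi_tau = tau
            factor = min(2.0, max(0.5, target / apd))
            tau_new = tau * factor
            if lo_tau is not None and hi_tau is not None:
                tau_new = 0.5 * (lo_tau + hi_tau)
            tau = tau_new
            params = set_tau(params, tau)
            apd = _cable_apd(params, region_label, bcl, n_s1)
        raise RuntimeError(
            f"APD calibration did not converge: target {target} ms, "
            f"reached {apd:.1f} ms at tau_close={tau:.2f} ms"
        )

    if "myo" in targets:
        params = solve(
            MYO,
            lambda p: p.ionic_myo.tau_close,
            lambda p, tau: replace(p, ionic_myo=replace(p.ionic_myo, tau_close=tau)),
            targets["myo"],
        )
    if "bz" in targets:
        params = solve(
            BZ,
            lambda p: p.ionic_bz.tau_close,
            lambda p, tau: replace(p, bz_apd_prolongation=tau / p.ionic_myo.tau_close),
            targets["bz"],
        )
    return params


def conduction_velocity(mesh: LabeledMesh, result: SimResult, beat: int,
                        axis: int = 0, frac: tuple[float, float] = (0.3, 0.7)
                        ) -> float:
    """Plane-wave conduction velocity (mm/ms) from ATs at two stations.

    Uses the activation-time difference between two cross-sections at the
    given fractions of the domain extent along ``axis``.
    """
    coords = mesh.nodes[:, axis]
    lo, hi = coords.min(), coords.max()
    x1 = lo + frac[0] * (hi - lo)
    x2 = lo + frac[1] * (hi - lo)
    at = result.node_at[beat]

    def station_at(x: float) -> float:
        sel = np.abs(coords - x) <= mesh.resolution / 2 + 1e-9
        vals = at[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("no activation at the requested station")
        return float(np.median(vals))

    return (x2 - x1) / (station_at(x2) - station_at(x1))
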