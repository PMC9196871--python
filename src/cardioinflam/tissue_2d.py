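"""2-D monodomain sheet: inflammation scenarios, reentry, critical pacing rate.

Sheets are parameterized stand-ins for realistic ventricular slices: the
transmural direction runs along x (endocardial edge at x = 0, layer bands
25:35:40 ENDO:MID:EPI), pacing mimics Purkinje breakthrough on the
endocardial edge, an optional non-conducting obstacle plays the role of
the ventricular-cavity ring that supports anatomical reentry, and a
rectangular lesion on the free wall hosts local inflammation (severity-1
cytokine perturbation plus a 35% coupling reduction).  Global inflammation
applies the same perturbation to every tissue node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels as K
from .ap_analysis import steady_state
from .cell_model import SolverInstabilityError, Variant, default_parameters
from .inflammation import apply_perturbation, severity_preset
from .tissue_1d import (ConductionClass, D_NORMAL, StrandGeometry,
                        conduction_class, s1_snapshot, variant_layout)


@dataclass(frozen=True)
class SheetStimulus:
    """Rectangular pulse on grid columns [x0, x1) and rows [y0, y1)."""

    start: float
    duration: float = 2.0
    amplitude: float = 80.0
    x0: int = 0
    x1: int = 3
    y0: int = 0
    y1: int = 10**6  # clipped to ny


@dataclass
class SheetGeometry:
    """Masked grid with per-node variant, diffusion and cell parameters."""

    nx: int
    ny: int
    dx: float
    mask: np.ndarray          # (ny, nx) bool, conducting tissue
    D: np.ndarray             # (ny, nx) mm^2/ms
    node_params: np.ndarray   # (ny*nx, N_PARAM)
    lesion: np.ndarray        # (ny, nx) bool
    obstacle: np.ndarray      # (ny, nx) bool
    variants: np.ndarray      # (nx,) column layer labels (object array)
    severity_map: np.ndarray  # (ny, nx) float
    scenario: str = "control"

    def __post_init__(self) -> None:
        if np.any(self.lesion & ~self.mask):
            raise ValueError("lesion must lie inside conducting tissue")
        if np.any(self.obstacle & self.mask):
            raise ValueError("obstacle must not intersect conducting tissue")
        if np.any(self.D[self.mask] <= 0):
            raise ValueError("D must be positive on tissue")


def build_sheet(scenario: str = "control", nx: int = 60, ny: int = 60,
                dx: float = 0.15, D: float = D_NORMAL,
                severity: float = 1.0, lesion_frac: float = 1.0 / 3.0,
                obstacle: bool = False, obstacle_radius_frac: float = 0.12,
                pacing_cols: int = 2,
                rng: Optional[np.random.Generator] = None) -> SheetGeometry:
    """Deterministic sheet geometry for a named scenario.

    ``scenario``: 'control' (no perturbed nodes), 'local' (rectangular
    free-wall lesion of ``lesion_frac`` of each dimension, perturbed at
    ``severity`` with 35%-per-severity coupling loss), or 'global' (every
    tissue node perturbed).  ``rng`` only jitters the lesion placement by a
    couple of nodes; geometry is deterministic without it.
    """
    if scenario not in ("control", "local", "global"):
        raise ValueError(f"unknown scenario {scenario!r}")
    mask = np.ones((ny, nx), dtype=bool)
    obstacle_mask = np.zeros((ny, nx), dtype=bool)
    if obstacle:
        cy, cx = ny / 2.0, nx * 0.45
        r = obstacle_radius_frac * min(nx, ny)
        yy, xx = np.mgrid[0:ny, 0:nx]
        obstacle_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        mask &= ~obstacle_mask

    lesion = np.zeros((ny, nx), dtype=bool)
    if scenario == "local":
        w = max(1, int(round(lesion_frac * nx)))
        h = max(1, int(round(lesion_frac * ny)))
        x0 = int(round(0.60 * nx))
        y0 = (ny - h) // 2
        if rng is not None:
            x0 += int(rng.integers(-2, 3))
            y0 += int(rng.integers(-2, 3))
        x0 = min(max(x0, pacing_cols + 1), nx - w)
        y0 = min(max(y0, 0), ny - h)
        lesion[y0:y0 + h, x0:x0 + w] = True
        lesion &= mask
        if np.any(lesion[:, :pacing_cols]):
            raise ValueError("lesion overlaps the pacing columns")
    elif scenario == "global":
        lesion = mask.copy()

    sev = np.zeros((ny, nx))
    sev[lesion] = severity
    pert = severity_preset(severity)
    base = {v: default_parameters(v).to_array() for v in Variant}
    infl = {v: apply_perturbation(default_parameters(v), pert).to_array()
            for v in Variant}
    layout = variant_layout(nx)
    P = np.empty((ny * nx, K.N_PARAM))
    for y in range(ny):
        for x in range(nx):
            v = layout[x]
            P[y * nx + x] = infl[v] if lesion[y, x] else base[v]
    D_arr = np.full((ny, nx), D)
    D_arr[lesion] = D * pert.diffusion_scale
    return SheetGeometry(nx=nx, ny=ny, dx=dx, mask=mask, D=D_arr,
                         node_params=P, lesion=lesion, obstacle=obstacle_mask,
                         variants=np.array(layout, dtype=object),
                         severity_map=sev, scenario=scenario)


def endo_pacing(n_beats: int, period: float = 1000.0, amplitude: float = 80.0,
                duration: float = 2.0, cols: int = 3) -> List[SheetStimulus]:
    """Supra-threshold stimuli on the endocardial (x = 0) edge.

    A 3-column, 2 ms pulse; the 0.5 ms single-cell pulse under-delivers
    charge against the 2-D electrotonic load at the pacing strip.
    """
    return [SheetStimulus(start=i * period, duration=duration,
                          amplitude=amplitude, x0=0, x1=cols)
            for i in range(n_beats)]


@dataclass
class SheetRecording:
    """Vm(t, y, x) snapshots (float32, decimated sampling)."""

    time: np.ndarray
    vm: np.ndarray            # (n_t, ny, nx)
    dx: float
    mask: np.ndarray
    final_states: Optional[np.ndarray] = None

    def activation_times(self, threshold: float = -20.0, start: float = 0.0,
                         end: Optional[float] = None) -> np.ndarray:
        t = self.time
        sel = (t >= start) if end is None else ((t >= start) & (t < end))
        tw = t[sel]
        vw = self.vm[sel]
        ny, nx = self.vm.shape[1:]
        out = np.full((ny, nx), np.nan)
        up = (vw[1:] >= threshold) & (vw[:-1] < threshold)
        for y in range(ny):
            for x in range(nx):
                if not self.mask[y, x]:
                    continue
                idx = np.nonzero(up[:, y, x])[0]
                if len(idx):
                    j = idx[0]
                    v0 = float(vw[j, y, x])
                    v1 = float(vw[j + 1, y, x])
                    lam = (threshold - v0) / (v1 - v0) if v1 != v0 else 0.0
                    out[y, x] = tw[j] + lam * (tw[j + 1] - tw[j])
        return out

    def activation_counts(self, threshold: float = -20.0,
                          start: float = 0.0) -> np.ndarray:
        sel = self.time >= start
        vw = self.vm[sel]
        up = (vw[1:] >= threshold) & (vw[:-1] < threshold)
        return up.sum(axis=0) * self.mask

    def write_snapshot_txt(self, fp, time_index: int = -1) -> None:
        """One Vm frame as plain gridded text (rows = y, columns = x)."""
        np.savetxt(fp, self.vm[time_index], fmt="%.3f",
                   header=f"t = {self.time[time_index]:.2f} ms")

    def write_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.time, compression="gzip")
            f.create_dataset("vm", data=self.vm, compression="gzip")
            f.create_dataset("mask", data=self.mask.astype(np.uint8),
                             compression="gzip")
            f.attrs["dx_mm"] = self.dx

    def last_activation_time(self, threshold: float = -20.0,
                             start: float = 0.0) -> float:
        sel = self.time >= start
        tw = self.time[sel]
        vw = self.vm[sel]
        up = (vw[1:] >= threshold) & (vw[:-1] < threshold)
        any_up = up.reshape(up.shape[0], -1).any(axis=1)
        idx = np.nonzero(any_up)[0]
        return float(tw[idx[-1] + 1]) if len(idx) else float("nan")


def sheet_initial_states(geometry: SheetGeometry,
                         prepace_beats: int = 200) -> np.ndarray:
    S = np.empty((geometry.ny * geometry.nx, K.N_STATE))
    layout = geometry.variants
    for y in range(geometry.ny):
        for x in range(geometry.nx):
            sev = float(geometry.severity_map[y, x])
            S[y * geometry.nx + x] = steady_state(layout[x], sev,
                                                  count=prepace_beats).to_array()
    return S


def solve_sheet(geometry: SheetGeometry, stimuli: Sequence[SheetStimulus],
                duration: float, dt: float = 0.02, record_dt: float = 2.0,
                initial: Optional[np.ndarray] = None,
                prepace_beats: int = 200) -> SheetRecording:
    """Integrate the monodomain sheet (5-point Laplacian, no-flux mask edges)."""
    ny, nx = geometry.ny, geometry.nx
    S = (np.array(initial, dtype=float) if initial is not None
         else sheet_initial_states(geometry, prepace_beats))
    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(record_dt / dt)))
    n_rec = (n_steps + rec_stride - 1) // rec_stride
    vrec = np.empty((n_rec, ny * nx), dtype=np.float32)
    st = list(stimuli)
    status, bad, bad_step, k = K.run_sheet(
        S, geometry.node_params, geometry.D.ravel(),
        geometry.mask.ravel().astype(np.uint8), nx, ny, geometry.dx, dt,
        n_steps,
        np.array([s.start for s in st], dtype=float),
        np.array([s.duration for s in st], dtype=float),
        np.array([s.amplitude for s in st], dtype=float),
        np.array([s.x0 for s in st], dtype=np.int64),
        np.array([min(s.x1, nx) for s in st], dtype=np.int64),
        np.array([s.y0 for s in st], dtype=np.int64),
        np.array([min(s.y1, ny) for s in st], dtype=np.int64),
        rec_stride, vrec, *K.tables_for(dt))
    if status != 0:
        raise SolverInstabilityError(
            f"instability at node ({bad // nx}, {bad % nx}), "
            f"t = {bad_step * dt:.2f} ms")
    t = dt * rec_stride * np.arange(k)
    return SheetRecording(time=t, vm=vrec[:k].reshape(k, ny, nx),
                          dx=geometry.dx, mask=geometry.mask, final_states=S)


def winding_circulation(act_times: np.ndarray, angles: np.ndarray,
                        min_span: float = 30.0) -> bool:
    """Heuristic circulation test on a ring of activation times.

    True when, ordered by angle around the ring, the activation times form
    a single monotone ramp with one wrap-around — the signature of a wave
    travelling once around the ring rather than invading from one side.
    """
    ok = np.isfinite(act_times)
    if ok.sum() < 6:
        return False
    a = act_times[ok]
    th = angles[ok]
    order = np.argsort(th)
    a = a[order]
    span = float(np.max(a) - np.min(a))
    if span < min_span:
        return False
    d = np.diff(np.concatenate([a, a[:1]]))
    j = int(np.argmax(np.abs(d)))
    rest = np.delete(d, j)
    if len(rest) == 0:
        return False
    sign = -np.sign(d[j])
    tol = 0.15 * span
    return bool(np.all(sign * rest >= -tol) and abs(d[j]) > 0.5 * span)


@dataclass
class ReentryResult:
    induced: bool
    reentry_type: str            # 'none' | 'functional' | 'anatomical'
    lifetime_ms: float
    activation_counts: Optional[np.ndarray] = None
    s2_coupling: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.lifetime_ms > 0) != self.induced and self.reentry_type != "none":
            raise ValueError("lifetime must be positive iff reentry was induced")


def _sheet_s1_snapshot(geometry: SheetGeometry, settle_beats: int = 3,
                       period: float = 1000.0, dt: float = 0.02,
                       prepace_beats: int = 200, stim_amplitude: float = 80.0,
                       stim_duration: float = 2.0,
                       stim_cols: int = 3) -> np.ndarray:
    rec = solve_sheet(geometry,
                      endo_pacing(settle_beats, period, amplitude=stim_amplitude,
                                  duration=stim_duration, cols=stim_cols),
                      duration=settle_beats * period, dt=dt, record_dt=10.0,
                      prepace_beats=prepace_beats)
    return rec.final_states


def _default_s2_rect(geometry: SheetGeometry) -> Tuple[int, int, int, int]:
    """S2 region: lesion border for local scenarios, epicardial patch else."""
    ny, nx = geometry.ny, geometry.nx
    if geometry.scenario == "local" and geometry.lesion.any():
        ys, xs = np.nonzero(geometry.lesion)
        x0 = int(xs.min()) - 2
        return (max(x0, 0), max(x0, 0) + 4, ny // 2 - ny // 8, ny // 2 + ny // 8)
    x0 = int(0.75 * nx)
    return (x0, x0 + 4, ny // 2 - ny // 8, ny // 2 + ny // 8)


def induce_reentry(geometry: SheetGeometry,
                   s2_rect: Optional[Tuple[int, int, int, int]] = None,
                   scan: Tuple[float, float, float] = (250.0, 450.0, 2.0),
                   follow_ms: float = 2000.0, period: float = 1000.0,
                   settle_beats: int = 2, dt: float = 0.02,
                   prepace_beats: int = 200,
                   base_state: Optional[np.ndarray] = None) -> ReentryResult:
    """S1-S2 reentry induction.

    Scans the S2 coupling interval in ``scan`` (min, max, step) until the
    premature wave blocks on its proximal (endocardial) side while escaping
    distally, then follows the episode for ``follow_ms``.  Reentry is
    scored when any node activates >= 3 times after S2; it is anatomical
    when the late activation circulates around the obstacle (winding test),
    functional otherwise.
    """
    ny, nx = geometry.ny, geometry.nx
    rect = s2_rect if s2_rect is not None else _default_s2_rect(geometry)
    x0, x1, y0, y1 = rect
    if base_state is None:
        base_state = _sheet_s1_snapshot(geometry, settle_beats, period, dt,
                                        prepace_beats)
    cx = (x0 + x1) // 2
    cy = (y0 + y1) // 2
    probe = 10
    lo, hi, step = scan

    # store the post-S1 evolution once so each S2 trial restarts mid-flight
    n_snap = int(round((hi - lo) / step)) + 1
    snaps = np.empty((n_snap, ny * nx, K.N_STATE))
    n_steps = int(round(hi / dt))
    S = base_state.copy()
    s1 = SheetStimulus(start=0.0)
    T, vmin_t, idv = K.tables_for(dt)
    status, bad, bad_step, _ = K.run_sheet_store(
        S, geometry.node_params, geometry.D.ravel(),
        geometry.mask.ravel().astype(np.uint8), nx, ny, geometry.dx, dt,
        n_steps, np.array([s1.start]), np.array([s1.duration]),
        np.array([s1.amplitude]),
        np.array([s1.x0], dtype=np.int64), np.array([min(s1.x1, nx)], dtype=np.int64),
        np.array([s1.y0], dtype=np.int64), np.array([min(s1.y1, ny)], dtype=np.int64),
        int(round(lo / dt)), max(1, int(round(step / dt))), snaps, T, vmin_t, idv)
    if status != 0:
        raise SolverInstabilityError(
            f"instability at node ({bad // nx}, {bad % nx}), "
            f"t = {bad_step * dt:.2f} ms")

    def state_at(coupling: float) -> np.ndarray:
        idx = int(round((coupling - lo) / step))
        return snaps[idx].copy()

    def s2_trial(coupling: float, duration: float) -> SheetRecording:
        stimuli = [SheetStimulus(start=0.0, x0=x0, x1=x1, y0=y0, y1=y1)]
        return solve_sheet(geometry, stimuli, duration, dt=dt, record_dt=2.0,
                           initial=state_at(coupling))

    def sides(coupling: float):
        rec = s2_trial(coupling, 120.0)
        at = rec.activation_times(start=1.0, end=100.0)
        left = not math.isnan(at[cy, max(cx - probe, 0)])
        right = not math.isnan(at[cy, min(cx + probe, nx - 1)])
        return left, right

    # couplings order BLOCK -> UNIDIRECTIONAL -> BIDIRECTIONAL as they grow;
    # bisect for the earliest coupling with any escape, then inspect it
    found = None
    l_lo, r_lo = sides(lo)
    if l_lo != r_lo:
        found = lo
    elif not (l_lo and r_lo):
        l_hi, r_hi = sides(hi)
        if l_hi != r_hi:
            found = hi
        elif l_hi and r_hi:
            b_lo, b_hi = lo, hi
            while b_hi - b_lo > step + 1e-9:
                mid = b_lo + step * round((0.5 * (b_lo + b_hi) - b_lo) / step)
                if mid <= b_lo or mid >= b_hi:
                    break
                l, r = sides(mid)
                if not (l or r):
                    b_lo = mid
                else:
                    b_hi = mid
            l, r = sides(b_hi)
            if l != r:
                found = b_hi
    if found is None:
        return ReentryResult(induced=False, reentry_type="none", lifetime_ms=0.0)

    rec = s2_trial(found, follow_ms)
    counts = rec.activation_counts(start=1.0)
    induced = bool(np.max(counts) >= 3)
    if not induced:
        return ReentryResult(induced=False, reentry_type="none", lifetime_ms=0.0,
                             activation_counts=counts, s2_coupling=found)
    lifetime = rec.last_activation_time(start=0.0)
    rtype = "functional"
    if geometry.obstacle.any():
        ring_y, ring_x, angles = obstacle_ring(geometry)
        last_act = _ring_last_activation(rec, ring_y, ring_x,
                                         start=0.5 * lifetime)
        if winding_circulation(last_act, angles):
            rtype = "anatomical"
    return ReentryResult(induced=True, reentry_type=rtype,
                         lifetime_ms=float(lifetime),
                         activation_counts=counts, s2_coupling=found)


def obstacle_ring(geometry: SheetGeometry) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tissue nodes bordering the obstacle, with their angles about its centroid."""
    obs = geometry.obstacle
    if not obs.any():
        raise ValueError("geometry has no obstacle")
    ny, nx = obs.shape
    ring = np.zeros_like(obs)
    shifted = np.zeros_like(obs)
    for dy, dx_ in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        s = np.roll(obs, (dy, dx_), axis=(0, 1))
        shifted |= s
    ring = shifted & geometry.mask
    ys, xs = np.nonzero(ring)
    cy, cx = np.nonzero(obs)
    cy, cx = cy.mean(), cx.mean()
    angles = np.arctan2(ys - cy, xs - cx)
    return ys, xs, angles


def _ring_last_activation(rec: SheetRecording, ys: np.ndarray, xs: np.ndarray,
                          start: float, threshold: float = -20.0) -> np.ndarray:
    sel = rec.time >= start
    tw = rec.time[sel]
    out = np.full(len(ys), np.nan)
    for k in range(len(ys)):
        v = rec.vm[sel, ys[k], xs[k]]
        up = np.nonzero((v[1:] >= threshold) & (v[:-1] < threshold))[0]
        if len(up):
            out[k] = tw[up[-1] + 1]
    return out


@dataclass
class CriticalPCLResult:
    """Minimum pacing cycle length with 1:1 conduction."""

    critical_pcl: float
    classes: Dict[float, ConductionClass]
    class_below: Optional[ConductionClass] = None

    @property
    def heart_rate_bpm(self) -> float:
        return 60000.0 / self.critical_pcl


def _pace_sheet_pcl(geometry: SheetGeometry, state: np.ndarray, pcl: float,
                    beats: int, sensor: Tuple[int, int], assess_last: int,
                    dt: float, stim_amplitude: float = 80.0,
                    stim_duration: float = 0.5,
                    stim_cols: int = 3) -> Tuple[np.ndarray, ConductionClass]:
    stimuli = [SheetStimulus(start=i * pcl, amplitude=stim_amplitude,
                             duration=stim_duration, x1=stim_cols)
               for i in range(beats)]
    rec = solve_sheet(geometry, stimuli, beats * pcl, dt=dt,
                      record_dt=1.0, initial=state)
    sy, sx = sensor
    sel = rec.time >= (beats - assess_last) * pcl
    v = rec.vm[sel, sy, sx]
    count = int(np.sum((v[1:] >= -20.0) & (v[:-1] < -20.0)))
    if count >= assess_last:
        cls = ConductionClass.ONE_TO_ONE
    elif abs(count - assess_last / 2) <= 1:
        cls = ConductionClass.TWO_TO_ONE
    else:
        cls = ConductionClass.FAILURE
    return rec.final_states, cls


def critical_pcl(geometry, pcl_range: Tuple[float, float] = (250.0, 450.0),
                 coarse_step: float = 10.0, refine_step: float = 1.0,
                 beats_per_pcl: int = 8, assess_last: int = 4,
                 sensor=None, dt: float = 0.02, prepace_beats: int = 200,
                 stim_amplitude: float = 80.0,
                 stim_duration: float = 0.5,
                 stim_cols: int = 3) -> CriticalPCLResult:
    """Minimum PCL sustaining 1:1 conduction (strand or sheet geometry).

    Mimics a gradual pacing-rate increase: starting from the 1 Hz steady
    state at the top of ``pcl_range``, the PCL is decremented in
    ``coarse_step`` steps with ``beats_per_pcl`` beats at each step,
    *carrying the tissue state* so action potentials accommodate to rate.
    When 1:1 conduction (scored over the last ``assess_last`` beats at a
    sensor far from the pacing edge) is first lost, the ramp restarts from
    the state saved at the last passing PCL and descends in
    ``refine_step`` steps.  The critical PCL is the lowest 1:1 PCL of the
    fine ramp.
    """
    from .tissue_1d import pace_strand_pcl

    if isinstance(geometry, StrandGeometry):
        state = s1_snapshot(geometry, prepace_beats=prepace_beats).copy()

        def run(state, pcl):
            return pace_strand_pcl(geometry, state, pcl, beats=beats_per_pcl,
                                   sensor=sensor, assess_last=assess_last,
                                   amplitude=stim_amplitude,
                                   duration=stim_duration, dt=dt)
    elif isinstance(geometry, SheetGeometry):
        state = _sheet_s1_snapshot(geometry, dt=dt, prepace_beats=prepace_beats,
                                   stim_amplitude=stim_amplitude,
                                   stim_duration=max(stim_duration, 2.0),
                                   stim_cols=stim_cols).copy()
        sens = sensor if sensor is not None else (geometry.ny // 2, geometry.nx - 10)

        def run(state, pcl):
            return _pace_sheet_pcl(geometry, state, pcl, beats_per_pcl, sens,
                                   assess_last, dt, stim_amplitude,
                                   stim_duration, stim_cols)
    else:
        raise TypeError(f"unsupported geometry {type(geometry).__name__}")

    lo, hi = pcl_range
    classes: Dict[float, ConductionClass] = {}

    def ramp(state, start, step):
        """Descend from ``start`` by ``step``; return (last-pass pcl, state,
        failing pcl) where state is the tissue state at the last pass."""
        pcl = start
        last_good = None
        good_state = None
        while pcl >= lo - 1e-9:
            prev = state.copy()
            state, cls = run(state, pcl)
            classes[round(pcl, 6)] = cls
            if cls != ConductionClass.ONE_TO_ONE:
                return last_good, good_state, pcl
            last_good, good_state = pcl, state.copy()
            pcl = round(pcl - step, 6)
        return last_good, good_state, None

    coarse_good, coarse_state, coarse_fail = ramp(state, hi, coarse_step)
    if coarse_good is None:
        raise RuntimeError(f"no 1:1 conduction at the top of the range; "
                           f"observed { {k: v.value for k, v in classes.items()} }")
    if coarse_fail is None:
        raise RuntimeError(f"conduction stayed 1:1 down to {lo} ms; "
                           f"observed { {k: v.value for k, v in classes.items()} }")
    fine_good, _, fine_fail = ramp(coarse_state.copy(),
                                   round(coarse_good - refine_step, 6),
                                   refine_step)
    critical = fine_good if fine_good is not None else coarse_good
    below = classes.get(round(fine_fail, 6)) if fine_fail is not None else \
        classes.get(round(coarse_fail, 6))
    return CriticalPCLResult(critical_pcl=critical, classes=dict(classes),
                             class_below=below)
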