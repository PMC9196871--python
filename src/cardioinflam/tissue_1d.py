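"""1-D transmural strand: monodomain cable, CV and the vulnerable window.

The default strand is 15 mm (100 nodes at dx = 0.15 mm) with a 25:35:40
ENDO:MID:EPI transmural layout, ENDO end first, diffusion coefficient
0.154 mm²/ms (0.1 mm²/ms in fully inflamed tissue).  The S1-S2 protocol
paces the first three ENDO-end nodes at 1 Hz and probes each measurement
site with a premature stimulus on a 0.45 mm (3-node) segment; scanning the
coupling interval Δt (anchored at the last S1 delivery) classifies the
response as bidirectional conduction, unidirectional block, or
bidirectional block, and the vulnerable window is the maximal contiguous
unidirectional-block interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels as K
from .ap_analysis import steady_state
from .cell_model import (CellParameters, SolverInstabilityError, Variant,
                         default_parameters)
from .inflammation import PerturbationSet, apply_perturbation, severity_preset

#: default diffusion coefficient, mm^2/ms (human, CV 0.74 m/s)
D_NORMAL = 0.154
#: diffusion coefficient of fully inflamed tissue, mm^2/ms (CV 0.6 m/s)
D_INFLAMED = 0.1

DEFAULT_PROPORTIONS = (0.25, 0.35, 0.40)  # ENDO : MID : EPI


@dataclass(frozen=True)
class Stimulus:
    """Rectangular current pulse on a contiguous node range [node_lo, node_hi)."""

    start: float          # ms
    duration: float = 0.5
    amplitude: float = 80.0  # pA/pF, depolarizing-positive
    node_lo: int = 0
    node_hi: int = 3


def s1_train(n_beats: int, period: float = 1000.0, amplitude: float = 80.0,
             duration: float = 0.5, node_lo: int = 0, node_hi: int = 3) -> List[Stimulus]:
    """S1 stimuli at the ENDO end (first three nodes by default)."""
    return [Stimulus(start=i * period, duration=duration, amplitude=amplitude,
                     node_lo=node_lo, node_hi=node_hi) for i in range(n_beats)]


@dataclass
class StrandGeometry:
    """Per-node variant labels, diffusion coefficients and cell parameters."""

    n_nodes: int
    dx: float
    variants: List[Variant]
    node_params: np.ndarray          # (n_nodes, N_PARAM)
    D: np.ndarray                    # (n_nodes,), mm^2/ms
    severity: float = 0.0
    inflamed: np.ndarray = field(default=None)  # bool mask

    def __post_init__(self) -> None:
        if self.inflamed is None:
            self.inflamed = np.zeros(self.n_nodes, dtype=bool)
        if np.any(self.D <= 0):
            raise ValueError("diffusion coefficient must be positive everywhere")
        if len(self.variants) != self.n_nodes or self.node_params.shape != (self.n_nodes, K.N_PARAM):
            raise ValueError("inconsistent geometry arrays")

    @property
    def length_mm(self) -> float:
        return self.n_nodes * self.dx


def variant_layout(n_nodes: int,
                   proportions: Sequence[float] = DEFAULT_PROPORTIONS) -> List[Variant]:
    """ENDO-first transmural layout with the given proportions."""
    n_endo = int(round(proportions[0] * n_nodes))
    n_mid = int(round(proportions[1] * n_nodes))
    layout = ([Variant.ENDO] * n_endo + [Variant.MID] * n_mid
              + [Variant.EPI] * (n_nodes - n_endo - n_mid))
    return layout


def build_strand(severity: float = 0.0, n_nodes: int = 100, dx: float = 0.15,
                 D: float = D_NORMAL, inflamed_D: float = D_INFLAMED,
                 proportions: Sequence[float] = DEFAULT_PROPORTIONS,
                 inflamed_mask: Optional[np.ndarray] = None,
                 perturbation: Optional[PerturbationSet] = None) -> StrandGeometry:
    """Default human transmural strand, optionally (partly) inflamed.

    ``severity`` applies the combined three-cytokine perturbation to the
    nodes in ``inflamed_mask`` (all nodes by default when severity > 0).
    Inflamed coupling interpolates linearly from ``D`` to ``inflamed_D``
    with severity, so full severity reproduces the reported 0.1 mm²/ms.
    """
    variants = variant_layout(n_nodes, proportions)
    mask = (np.ones(n_nodes, dtype=bool) if inflamed_mask is None
            else np.asarray(inflamed_mask, dtype=bool))
    if severity == 0.0 and perturbation is None:
        mask = np.zeros(n_nodes, dtype=bool)
    pert = perturbation if perturbation is not None else severity_preset(severity)
    base = {v: default_parameters(v) for v in Variant}
    inflamed_params = {v: apply_perturbation(base[v], pert) for v in Variant}
    P = np.empty((n_nodes, K.N_PARAM))
    for i, v in enumerate(variants):
        P[i] = (inflamed_params[v] if mask[i] else base[v]).to_array()
    D_arr = np.full(n_nodes, D)
    D_arr[mask] = D + pert.severity * (inflamed_D - D)
    return StrandGeometry(n_nodes=n_nodes, dx=dx, variants=variants,
                          node_params=P, D=D_arr, severity=pert.severity,
                          inflamed=mask)


@dataclass
class SpaceTimeRecording:
    """Vm(t, node) at a fixed sampling interval."""

    time: np.ndarray        # (n_t,), ms
    vm: np.ndarray          # (n_t, n_nodes)
    dx: float
    final_states: Optional[np.ndarray] = None  # (n_nodes, N_STATE)

    @property
    def n_nodes(self) -> int:
        return self.vm.shape[1]

    def activation_times(self, threshold: float = -20.0, start: float = 0.0,
                         end: Optional[float] = None) -> np.ndarray:
        """First upward threshold crossing per node in [start, end); NaN if none."""
        t = self.time
        sel = (t >= start) if end is None else ((t >= start) & (t < end))
        tw = t[sel]
        vw = self.vm[sel]
        out = np.full(self.n_nodes, np.nan)
        for i in range(self.n_nodes):
            v = vw[:, i]
            up = np.nonzero((v[1:] >= threshold) & (v[:-1] < threshold))[0]
            if len(up):
                j = up[0]
                lam = (threshold - v[j]) / (v[j + 1] - v[j])
                out[i] = tw[j] + lam * (tw[j + 1] - tw[j])
        return out

    def activation_count(self, node: int, threshold: float = -20.0,
                         start: float = 0.0) -> int:
        sel = self.time >= start
        v = self.vm[sel, node]
        return int(np.sum((v[1:] >= threshold) & (v[:-1] < threshold)))

    def write_csv(self, fp) -> None:
        """Wide CSV: one row per sample, columns time_ms, node_0, ..."""
        import csv as _csv
        w = _csv.writer(fp)
        w.writerow(["time_ms"] + [f"node_{i}" for i in range(self.n_nodes)])
        for k in range(len(self.time)):
            w.writerow([f"{self.time[k]:.3f}"]
                       + [f"{v:.4f}" for v in self.vm[k]])

    def write_hdf5(self, path) -> None:
        """Compressed binary export (gzip'd HDF5: /time, /vm, attrs dx)."""
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.time, compression="gzip")
            f.create_dataset("vm", data=self.vm, compression="gzip")
            f.attrs["dx_mm"] = self.dx

    @classmethod
    def read_hdf5(cls, path) -> "SpaceTimeRecording":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(time=f["time"][:], vm=f["vm"][:],
                       dx=float(f.attrs["dx_mm"]))


def initial_states(geometry: StrandGeometry, prepace_beats: int = 200,
                   period: float = 1000.0) -> np.ndarray:
    """Per-node single-cell pacing steady states (cached per variant/severity)."""
    S = np.empty((geometry.n_nodes, K.N_STATE))
    for i, v in enumerate(geometry.variants):
        sev = geometry.severity if geometry.inflamed[i] else 0.0
        S[i] = steady_state(v, sev, count=prepace_beats, period=period).to_array()
    return S


def solve_strand(geometry: StrandGeometry, stimuli: Iterable[Stimulus],
                 duration: float, dt: float = 0.02, record_dt: float = 0.5,
                 initial: Optional[np.ndarray] = None,
                 prepace_beats: int = 200) -> SpaceTimeRecording:
    """Integrate the monodomain cable and record Vm.

    Operator splitting (reaction then diffusion) at ``dt``; conservative
    flux form with harmonic-mean interface D; no-flux boundaries.  Aborts
    with :class:`SolverInstabilityError` if Vm leaves ±200 mV.
    """
    stimuli = list(stimuli)
    for s in stimuli:
        if s.start >= duration:
            raise ValueError(f"stimulus at {s.start} ms outside duration {duration} ms")
        if not (0 <= s.node_lo < s.node_hi <= geometry.n_nodes):
            raise ValueError("stimulus node range outside the strand")
    S = (np.array(initial, dtype=float) if initial is not None
         else initial_states(geometry, prepace_beats))
    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(record_dt / dt)))
    n_rec = (n_steps + rec_stride - 1) // rec_stride
    vrec = np.empty((n_rec, geometry.n_nodes))
    st_start = np.array([s.start for s in stimuli], dtype=float)
    st_dur = np.array([s.duration for s in stimuli], dtype=float)
    st_amp = np.array([s.amplitude for s in stimuli], dtype=float)
    st_lo = np.array([s.node_lo for s in stimuli], dtype=np.int64)
    st_hi = np.array([s.node_hi for s in stimuli], dtype=np.int64)
    T, vmin, idv = K.tables_for(dt)
    status, bad_node, bad_step, k = K.run_strand(
        S, geometry.node_params, geometry.D, geometry.dx, dt, n_steps,
        st_start, st_dur, st_amp, st_lo, st_hi, rec_stride, vrec, T, vmin, idv)
    if status != 0:
        raise SolverInstabilityError(
            f"instability at node {bad_node}, t = {bad_step * dt:.2f} ms")
    t = dt * rec_stride * np.arange(k)
    return SpaceTimeRecording(time=t, vm=vrec[:k], dx=geometry.dx, final_states=S)


def measure_cv(recording: SpaceTimeRecording, node_a: int = 20, node_b: int = 80,
               threshold: float = -20.0, start: float = 0.0) -> float:
    """Conduction velocity (m/s) from activation times of two interior nodes."""
    n = recording.n_nodes
    for node in (node_a, node_b):
        if not (10 <= node <= n - 11):
            raise ValueError(f"node {node} too close to a boundary")
    at = recording.activation_times(threshold=threshold, start=start)
    for node in (node_a, node_b):
        if math.isnan(at[node]):
            raise RuntimeError(f"node {node} never activated")
    dt_ms = at[node_b] - at[node_a]
    if dt_ms == 0:
        raise RuntimeError("zero activation-time difference")
    return abs(node_b - node_a) * recording.dx / dt_ms  # mm/ms == m/s


class S2Class(Enum):
    BIDIRECTIONAL = "bidirectional"
    UNIDIRECTIONAL_BLOCK = "unidirectional_block"
    BIDIRECTIONAL_BLOCK = "bidirectional_block"


def classify_s2(recording: SpaceTimeRecording, s2_site: int, s2_time: float,
                span: int = 10, window: float = 100.0,
                threshold: float = -20.0) -> S2Class:
    """Classify the S2 response by propagation ``span`` nodes to each side.

    A side counts as conducting if the node ``span`` nodes away from the
    S2 segment activates within ``window`` ms after S2 onset.
    """
    n = recording.n_nodes
    left = s2_site - span
    right = s2_site + span
    if left < 0 or right > n - 1:
        raise ValueError(f"s2 site {s2_site}: fewer than {span} nodes on one side")
    sel = (recording.time >= s2_time) & (recording.time < s2_time + window)
    t = recording.time[sel]
    conducted = []
    for node in (left, right):
        v = recording.vm[sel, node]
        up = np.nonzero((v[1:] >= threshold) & (v[:-1] < threshold))[0]
        conducted.append(len(up) > 0)
    if all(conducted):
        return S2Class.BIDIRECTIONAL
    if any(conducted):
        return S2Class.UNIDIRECTIONAL_BLOCK
    return S2Class.BIDIRECTIONAL_BLOCK


def s1_snapshot(geometry: StrandGeometry, settle_beats: int = 3,
                period: float = 1000.0, amplitude: float = 80.0,
                duration: float = 0.5, dt: float = 0.02,
                prepace_beats: int = 200) -> np.ndarray:
    """Strand state at the instant the next S1 is due, after settling beats."""
    rec = solve_strand(geometry, s1_train(settle_beats, period, amplitude, duration),
                       duration=settle_beats * period, dt=dt, record_dt=5.0,
                       prepace_beats=prepace_beats)
    return rec.final_states


@dataclass(frozen=True)
class VWScan:
    """Coupling-interval scan settings (ms, anchored at last S1 delivery)."""

    dt_min: float = 200.0
    dt_max: float = 650.0
    coarse: float = 5.0
    step: float = 1.0
    refine: float = 0.25
    window: float = 100.0
    #: premature-stimulus pulse.  The S1 pulse (80 pA/pF x 0.5 ms) cannot
    #: capture mid-cable against the electrotonic load of recovered
    #: neighbours (a 2 ms pulse captures the default strand from ~45-50
    #: pA/pF).  S2 uses twice the S1 amplitude at 2 ms, which lies in the
    #: saturation plateau where the measured window width is a property of
    #: tissue refractoriness, insensitive to further amplitude increases;
    #: see the methods note for the measured sensitivity.
    s2_duration: float = 2.0
    s2_amplitude: float = 160.0


@dataclass
class VWResult:
    """Vulnerable-window interval at one site."""

    site: int
    open: float
    close: float
    width: float
    classes: Dict[float, S2Class] = field(default_factory=dict)

    @property
    def found(self) -> bool:
        return self.width > 0 and not math.isnan(self.open)


@dataclass
class S1Trajectory:
    """Stored post-S1 strand states at ``snap_dt`` resolution.

    Lets an S2 trial restart at any coupling interval (a multiple of
    ``snap_dt``) without re-integrating the S1 episode.
    """

    snaps: np.ndarray   # (n_snap, n_nodes, N_STATE)
    snap_dt: float

    def state_at(self, t: float) -> np.ndarray:
        idx = int(round(t / self.snap_dt))
        if not (0 <= idx < self.snaps.shape[0]):
            raise ValueError(f"no snapshot at t = {t} ms")
        if abs(idx * self.snap_dt - t) > 1e-6:
            raise ValueError(f"t = {t} ms is not on the {self.snap_dt} ms grid")
        return self.snaps[idx].copy()


def s1_trajectory(geometry: StrandGeometry, base_state: np.ndarray,
                  s1: Stimulus, t_max: float, snap_dt: float = 0.25,
                  dt: float = 0.02) -> S1Trajectory:
    """Integrate one S1 from ``base_state`` storing snapshots every ``snap_dt``."""
    S = np.array(base_state, dtype=float)
    n_steps = int(round(t_max / dt))
    snap_stride = max(1, int(round(snap_dt / dt)))
    n_snap = n_steps // snap_stride + 1
    snaps = np.empty((n_snap, geometry.n_nodes, K.N_STATE))
    T, vmin, idv = K.tables_for(dt)
    status, bad, bad_step, _ = K.run_strand_store(
        S, geometry.node_params, geometry.D, geometry.dx, dt, n_steps,
        np.array([s1.start]), np.array([s1.duration]), np.array([s1.amplitude]),
        np.array([s1.node_lo], dtype=np.int64),
        np.array([s1.node_hi], dtype=np.int64),
        snap_stride, snaps, T, vmin, idv)
    if status != 0:
        raise SolverInstabilityError(
            f"instability at node {bad}, t = {bad_step * dt:.2f} ms")
    return S1Trajectory(snaps=snaps, snap_dt=snap_dt)


def _s2_trial(geometry: StrandGeometry, traj: S1Trajectory, site: int,
              coupling: float, s1: Stimulus, scan: VWScan, dt: float,
              cache: Dict[float, S2Class]) -> S2Class:
    if coupling in cache:
        return cache[coupling]
    seg_lo = site - 1
    seg_hi = site + 2  # 3 nodes = 0.45 mm at dx 0.15
    stimuli = [Stimulus(start=0.0, duration=scan.s2_duration,
                        amplitude=scan.s2_amplitude, node_lo=seg_lo, node_hi=seg_hi)]
    rec = solve_strand(geometry, stimuli, scan.window + 20.0, dt=dt,
                       record_dt=0.5, initial=traj.state_at(coupling))
    c = classify_s2(rec, site, 0.0, window=scan.window)
    cache[coupling] = c
    return c


def s2_response(geometry: StrandGeometry, site: int, coupling: float,
                s1: Optional[Stimulus] = None, scan: VWScan = VWScan(),
                trajectory: Optional[S1Trajectory] = None,
                base_state: Optional[np.ndarray] = None,
                dt: float = 0.02) -> S2Class:
    """Classify a single S2 coupling interval at one site."""
    s1 = s1 or Stimulus(start=0.0)
    if trajectory is None:
        if base_state is None:
            base_state = s1_snapshot(geometry)
        trajectory = s1_trajectory(geometry, base_state, s1, scan.dt_max,
                                   scan.refine, dt)
    return _s2_trial(geometry, trajectory, site, coupling, s1, scan, dt, {})


def _bisect_edge(classify, lo: float, hi: float, want_hi: S2Class,
                 refine: float) -> float:
    """Edge between classes: classify(lo) != want_hi, classify(hi) == want_hi."""
    while hi - lo > refine + 1e-9:
        mid = 0.5 * (lo + hi)
        mid = round(mid / refine) * refine
        if mid <= lo or mid >= hi:
            break
        if classify(mid) == want_hi:
            hi = mid
        else:
            lo = mid
    return hi


def measure_vw(geometry: StrandGeometry, site: int,
               s1: Optional[Stimulus] = None, scan: VWScan = VWScan(),
               base_state: Optional[np.ndarray] = None,
               trajectory: Optional[S1Trajectory] = None,
               dt: float = 0.02) -> VWResult:
    """Vulnerable window at one site via S2 coupling-interval scanning.

    An adaptive coarse pass brackets the refractory→recovered transition,
    a 1 ms scan locates the maximal contiguous unidirectional-block run,
    and bisection refines both edges to 0.25 ms.  If no unidirectional
    interval exists the result has width 0 and NaN edges.
    """
    s1 = s1 or Stimulus(start=0.0)
    if trajectory is None:
        if base_state is None:
            base_state = s1_snapshot(geometry)
        trajectory = s1_trajectory(geometry, base_state, s1, scan.dt_max,
                                   scan.refine, dt)
    cache: Dict[float, S2Class] = {}

    def cls(c: float) -> S2Class:
        return _s2_trial(geometry, trajectory, site, c, s1, scan, dt, cache)

    # coarse pass: bracket the end of absolute refractoriness
    lo = None
    hi = None
    if (cls(scan.dt_min) == S2Class.BIDIRECTIONAL_BLOCK
            and cls(scan.dt_max) == S2Class.BIDIRECTIONAL):
        b_lo, b_hi = scan.dt_min, scan.dt_max
        while b_hi - b_lo > scan.coarse + 1e-9:
            mid = b_lo + scan.coarse * round((0.5 * (b_lo + b_hi) - b_lo) / scan.coarse)
            if mid <= b_lo or mid >= b_hi:
                break
            if cls(mid) == S2Class.BIDIRECTIONAL_BLOCK:
                b_lo = mid
            else:
                b_hi = mid
        lo = b_lo
        # walk forward to the first fully recovered coupling
        t_bi = b_hi
        while cls(t_bi) != S2Class.BIDIRECTIONAL and t_bi < scan.dt_max - 1e-9:
            t_bi = min(t_bi + scan.coarse, scan.dt_max)
        hi = t_bi
    else:
        # fallback: plain coarse sweep (degenerate refractoriness at the ends)
        t_last_block = None
        t_recovered = None
        c = scan.dt_min
        while c <= scan.dt_max + 1e-9:
            k = cls(c)
            if k == S2Class.BIDIRECTIONAL_BLOCK:
                t_last_block = c
            elif k == S2Class.BIDIRECTIONAL:
                t_recovered = c
                break
            c += scan.coarse
        lo = t_last_block if t_last_block is not None else scan.dt_min
        hi = t_recovered if t_recovered is not None else scan.dt_max

    # dense pass at the spec'd resolution over the bracketed range
    grid = np.arange(lo, hi + scan.step / 2, scan.step)
    classes = [cls(round(float(g), 6)) for g in grid]
    uni = [i for i, k in enumerate(classes) if k == S2Class.UNIDIRECTIONAL_BLOCK]
    if not uni:
        return VWResult(site=site, open=float("nan"), close=float("nan"),
                        width=0.0, classes=dict(cache))
    # maximal contiguous run
    runs: List[Tuple[int, int]] = []
    s = uni[0]
    prev = uni[0]
    for i in uni[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((s, prev))
            s = i
            prev = i
    runs.append((s, prev))
    i0, i1 = max(runs, key=lambda r: r[1] - r[0])
    open_edge = float(grid[i0])
    close_edge = float(grid[i1])
    if i0 > 0:
        open_edge = _bisect_edge(cls, float(grid[i0 - 1]), open_edge,
                                 S2Class.UNIDIRECTIONAL_BLOCK, scan.refine)
    if i1 < len(grid) - 1:
        # refine where UNI ends: bisect for the first non-UNI coupling
        first_non = _bisect_edge(
            lambda c: (S2Class.BIDIRECTIONAL
                       if cls(c) != S2Class.UNIDIRECTIONAL_BLOCK
                       else S2Class.UNIDIRECTIONAL_BLOCK),
            close_edge, float(grid[i1 + 1]), S2Class.BIDIRECTIONAL, scan.refine)
        close_edge = first_non - scan.refine
    return VWResult(site=site, open=open_edge, close=close_edge,
                    width=max(0.0, close_edge - open_edge), classes=dict(cache))


@dataclass
class AverageVWResult:
    mean_width: float
    per_site: Dict[int, float]
    results: List[VWResult]


def average_vw(geometry: StrandGeometry, sites: Optional[Sequence[int]] = None,
               s1: Optional[Stimulus] = None, scan: VWScan = VWScan(),
               dt: float = 0.02,
               base_state: Optional[np.ndarray] = None) -> AverageVWResult:
    """Mean vulnerable-window width over measurement sites.

    Default sites subsample the strand interior (every 5th node, nodes
    10-85) so both classification probes stay 10 nodes inside the strand.
    """
    if sites is None:
        sites = list(range(10, 90, 5))
    if base_state is None:
        base_state = s1_snapshot(geometry)
    traj = s1_trajectory(geometry, base_state, s1 or Stimulus(start=0.0),
                         scan.dt_max, scan.refine, dt)
    results = [measure_vw(geometry, s, s1=s1, scan=scan,
                          trajectory=traj, dt=dt) for s in sites]
    widths = {r.site: r.width for r in results}
    return AverageVWResult(mean_width=float(np.mean(list(widths.values()))),
                           per_site=widths, results=results)


class ConductionClass(Enum):
    ONE_TO_ONE = "1:1"
    TWO_TO_ONE = "2:1"
    FAILURE = "failure"


def _classify_count(count: int, assess_last: int) -> ConductionClass:
    if count >= assess_last:
        return ConductionClass.ONE_TO_ONE
    if abs(count - assess_last / 2) <= 1:
        return ConductionClass.TWO_TO_ONE
    return ConductionClass.FAILURE


def pace_strand_pcl(geometry: StrandGeometry, state: np.ndarray, pcl: float,
                    beats: int = 8, sensor: Optional[int] = None,
                    assess_last: int = 4, amplitude: float = 80.0,
                    duration: float = 0.5,
                    dt: float = 0.02) -> Tuple[np.ndarray, ConductionClass]:
    """Pace ``beats`` beats at one PCL, carrying tissue state.

    Counts propagated wavefronts at a distal sensor over the last
    ``assess_last`` beats and returns the updated state with the
    conduction class (1:1, 2:1 or failure).  Meant to be chained across a
    descending PCL ramp so the tissue accommodates to rate, as in a
    gradual pacing-rate increase.
    """
    if sensor is None:
        sensor = geometry.n_nodes - 10
    stimuli = [Stimulus(start=i * pcl, duration=duration, amplitude=amplitude)
               for i in range(beats)]
    rec = solve_strand(geometry, stimuli, beats * pcl, dt=dt, record_dt=1.0,
                       initial=state)
    count = rec.activation_count(sensor, start=(beats - assess_last) * pcl)
    return rec.final_states, _classify_count(count, assess_last)


def conduction_class(geometry: StrandGeometry, pcl: float, beats: int = 8,
                     sensor: Optional[int] = None, assess_last: int = 4,
                     amplitude: float = 80.0, duration: float = 0.5,
                     dt: float = 0.02,
                     base_state: Optional[np.ndarray] = None) -> ConductionClass:
    """Conduction pattern at one PCL starting from the 1 Hz steady state."""
    if base_state is None:
        base_state = s1_snapshot(geometry)
    _, cls = pace_strand_pcl(geometry, base_state.copy(), pcl, beats=beats,
                             sensor=sensor, assess_last=assess_last,
                             amplitude=amplitude, duration=duration, dt=dt)
    return cls
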