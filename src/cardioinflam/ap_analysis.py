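"""Single-cell pacing experiments and action-potential metrics.

Drives a cell model to its pacing steady state, extracts APD at a
configurable repolarization fraction (APD90 by default), the transmural
APD dispersion between MID and ENDO/EPI cells, and calcium-handling
summary metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from . import _kernels as K
from .cell_model import (CellParameters, CellState, SolverInstabilityError,
                         Variant, default_parameters)
from .inflammation import PerturbationSet, apply_perturbation


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic stimulus train (amplitude stored positive, depolarizing)."""

    amplitude: float = 80.0   # pA/pF
    duration: float = 0.5     # ms
    period: float = 1000.0    # ms
    count: int = 1000         # beats to pacing steady state

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.duration >= self.period:
            raise ValueError("stimulus duration must be below the period")


@dataclass
class APTrace:
    """The final beats of a paced run, sampled uniformly.

    ``beat_starts`` are the stimulus-onset times (ms) of the recorded
    beats; ``steady_state`` reports the |ΔAPD90| < 1 ms criterion between
    the last two recorded beats when two are available.
    """

    time: np.ndarray
    vm: np.ndarray
    ca_i: np.ndarray
    ca_sr: np.ndarray
    period: float
    beat_starts: np.ndarray
    steady_state: bool = False
    apd_delta_last: float = float("nan")
    final_state: Optional[CellState] = None

    def __post_init__(self) -> None:
        if len(self.time) < 2 or np.any(np.diff(self.time) <= 0):
            raise ValueError("trace time must be strictly increasing")
        if len(self.beat_starts) < 1:
            raise ValueError("trace must contain at least one full beat")

    def beat_slice(self, beat: int) -> slice:
        """Sample range of recorded beat ``beat`` (negative indexes ok)."""
        starts = list(self.beat_starts) + [self.beat_starts[-1] + self.period]
        t0 = starts[:-1][beat]
        t1 = starts[1:][beat] if beat != -1 else starts[-1]
        i0 = int(np.searchsorted(self.time, t0 - 1e-9))
        i1 = int(np.searchsorted(self.time, t1 - 1e-9))
        return slice(i0, min(i1, len(self.time)))


def pace(params: CellParameters, protocol: PacingProtocol = PacingProtocol(),
         n_keep: int = 2, dt: float = 0.02, record_dt: float = 0.1,
         initial_state: Optional[CellState] = None) -> APTrace:
    """Run ``protocol.count`` beats and return the final ``n_keep`` beats.

    Recording is at ``record_dt`` (0.1 ms default).  The steady-state
    criterion |APD90(last) − APD90(second-last)| < 1 ms is evaluated on the
    recorded tail whenever it holds at least two beats.
    """
    n_rec_beats = min(max(n_keep, 2), protocol.count)
    state0 = initial_state if initial_state is not None else CellState()
    S = state0.to_array().reshape(1, -1)
    P = params.to_array().reshape(1, -1)
    record_from = (protocol.count - n_rec_beats) * protocol.period
    n_samples = int(round(n_rec_beats * protocol.period / record_dt)) + 1
    vrec = np.empty(n_samples)
    cair = np.empty(n_samples)
    casrr = np.empty(n_samples)
    T, vmin, idv = K.tables_for(dt)
    status, k, bad = K.pace_cell(S, P, dt, protocol.period, protocol.count,
                                 protocol.amplitude, protocol.duration,
                                 record_from, record_dt, vrec, cair, casrr,
                                 T, vmin, idv)
    if status != 0:
        beat = int(bad * dt // protocol.period)
        raise SolverInstabilityError(f"instability during pacing at beat {beat}")
    t = record_from + record_dt * np.arange(k)
    starts = record_from + protocol.period * np.arange(n_rec_beats)
    trace = APTrace(time=t, vm=vrec[:k], ca_i=cair[:k], ca_sr=casrr[:k],
                    period=protocol.period, beat_starts=starts,
                    final_state=CellState.from_array(S[0]))
    if n_rec_beats >= 2:
        a_last = apd(trace, beat=-1)
        a_prev = apd(trace, beat=-2)
        if not (a_last.repolarization_failure or a_prev.repolarization_failure):
            trace.apd_delta_last = abs(a_last.apd90 - a_prev.apd90)
            trace.steady_state = trace.apd_delta_last < 1.0
    if n_keep < n_rec_beats:
        sl = trace.beat_slice(-n_keep)
        i0 = sl.start
        trace = APTrace(time=trace.time[i0:], vm=trace.vm[i0:],
                        ca_i=trace.ca_i[i0:], ca_sr=trace.ca_sr[i0:],
                        period=trace.period, beat_starts=starts[-n_keep:],
                        steady_state=trace.steady_state,
                        apd_delta_last=trace.apd_delta_last,
                        final_state=trace.final_state)
    return trace


@dataclass(frozen=True)
class APDMeasurement:
    """APD at a repolarization fraction, with per-beat reference voltages."""

    apd90: float
    resting_vm: float
    peak_vm: float
    beat_index: int
    fraction: float = 0.9
    repolarization_failure: bool = False

    def __post_init__(self) -> None:
        if not self.repolarization_failure and self.peak_vm <= self.resting_vm:
            raise ValueError("peak Vm must exceed resting Vm")


def apd(trace: APTrace, fraction: float = 0.9, beat: int = -1) -> APDMeasurement:
    """APD at ``fraction`` repolarization for one recorded beat.

    Measured from the time of maximum upstroke dVm/dt to the downward
    crossing of ``Vrest + (1−fraction)·(Vpeak − Vrest)``, with linear
    interpolation between samples.  ``Vrest`` is Vm at the start of the
    beat window, ``Vpeak`` the in-beat maximum.  If the trace never
    recrosses the threshold before the next stimulus the measurement is
    flagged as a repolarization failure and APD is NaN.
    """
    sl = trace.beat_slice(beat)
    t = trace.time[sl]
    v = trace.vm[sl]
    if len(t) < 3:
        raise ValueError("beat window too short")
    v_rest = float(v[0])
    v_peak = float(np.max(v))
    idx = int(np.argmax(np.diff(v) / np.diff(t)))
    t_up = float(t[idx])
    thr = v_rest + (1.0 - fraction) * (v_peak - v_rest)
    i_peak = int(np.argmax(v))
    below = np.nonzero(v[i_peak:] < thr)[0]
    bi = beat if beat >= 0 else len(trace.beat_starts) + beat
    if len(below) == 0:
        return APDMeasurement(apd90=float("nan"), resting_vm=v_rest,
                              peak_vm=v_peak, beat_index=bi, fraction=fraction,
                              repolarization_failure=True)
    ic = i_peak + below[0]
    # linear interpolation across the crossing sample pair
    t_cross = float(t[ic])
    if ic > 0 and v[ic - 1] != v[ic]:
        lam = (v[ic - 1] - thr) / (v[ic - 1] - v[ic])
        t_cross = float(t[ic - 1] + lam * (t[ic] - t[ic - 1]))
    return APDMeasurement(apd90=t_cross - t_up, resting_vm=v_rest,
                          peak_vm=v_peak, beat_index=bi, fraction=fraction)


@dataclass(frozen=True)
class DeltaAPD:
    """Transmural APD dispersion between the MID cell and ENDO/EPI cells."""

    mid_minus_mean: float
    mid_minus_max: float

    def value(self, definition: str = "mean") -> float:
        if definition == "mean":
            return self.mid_minus_mean
        if definition == "max":
            return self.mid_minus_max
        raise ValueError(f"unknown ΔAPD definition {definition!r}")


def delta_apd(mid: float, endo: float, epi: float) -> DeltaAPD:
    """Both conventions of the MID-vs-(ENDO, EPI) APD difference (ms)."""
    if min(mid, endo, epi) <= 0:
        raise ValueError("APDs must be positive")
    return DeltaAPD(mid_minus_mean=mid - 0.5 * (endo + epi),
                    mid_minus_max=mid - max(endo, epi))


def calcium_metrics(trace: APTrace, beat: int = -1) -> dict:
    """Per-beat calcium summary: diastolic/systolic Ca_i and SR content."""
    sl = trace.beat_slice(beat)
    ca = trace.ca_i[sl]
    sr = trace.ca_sr[sl]
    return {
        "diastolic_ca_i": float(np.min(ca)),
        "systolic_ca_i": float(np.max(ca)),
        "ca_sr_content": float(np.min(sr)),
    }


@lru_cache(maxsize=64)
def _steady_cached(variant: str, severity: float, count: int, period: float,
                   amplitude: float, duration: float) -> tuple:
    from .inflammation import severity_preset
    params = apply_perturbation(default_parameters(variant),
                                severity_preset(severity))
    trace = pace(params, PacingProtocol(amplitude=amplitude, duration=duration,
                                        period=period, count=count))
    return tuple(trace.final_state.to_array())


def steady_state(variant: Variant | str, severity: float = 0.0,
                 count: int = 200, period: float = 1000.0,
                 amplitude: float = 80.0, duration: float = 0.5) -> CellState:
    """Cached pacing steady state of a (variant, severity) combination.

    Used to initialize tissue nodes so strand/sheet runs need only a few
    settling beats.
    """
    arr = _steady_cached(Variant(variant).value, severity, count, period,
                         amplitude, duration)
    return CellState.from_array(np.array(arr))
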