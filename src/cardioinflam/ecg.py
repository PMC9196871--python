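"""Pseudo-ECG from a space-time recording and QT-interval measurement.

The far-field unipolar potential at a virtual electrode is the dipole
source integral

    φ = (a² σ_i / 4 σ_e) ∫ (−∇Vm) · ∇(1/r) dΩ,

evaluated with central-difference Vm gradients on the grid (one-sided at
boundaries).  Only the σ_i/σ_e ratio and the lumped radius constant scale
the amplitude; timing quantities (QRS onset, T-wave end, QT) are amplitude
independent.  The default electrode sits 20 mm beyond the epicardial end
of a strand on its axis, a conventional virtual-electrode distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np

from .tissue_1d import SpaceTimeRecording
from .tissue_2d import SheetRecording


@dataclass(frozen=True)
class ECGSettings:
    """Virtual-electrode position (mm) and lumped amplitude constants."""

    electrode_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    a: float = 1.0
    sigma_i: float = 1.0
    sigma_e: float = 1.0

    @property
    def gain(self) -> float:
        return self.a ** 2 * self.sigma_i / (4.0 * self.sigma_e)


def default_strand_electrode(recording: SpaceTimeRecording,
                             distance_mm: float = 20.0) -> ECGSettings:
    """Electrode ``distance_mm`` beyond the EPI end, on the strand axis."""
    length = recording.n_nodes * recording.dx
    return ECGSettings(electrode_mm=(length + distance_mm, 0.0, 0.0))


@dataclass
class ECGTrace:
    time: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        if self.time.shape != self.phi.shape:
            raise ValueError("time and phi must have equal length")


def _gradient_terms_1d(vm: np.ndarray, x: np.ndarray, xe: float) -> np.ndarray:
    # (-dV/dx) * d(1/r)/dx summed over nodes; r = |xe - x| on the axis
    dvdx = np.gradient(vm, x, axis=1)
    r = np.abs(xe - x)
    geom = np.sign(xe - x) / r ** 2   # d(1/|xe-x|)/dx
    return (-dvdx) * geom[None, :]


def pseudo_ecg(recording: Union[SpaceTimeRecording, SheetRecording],
               settings: Optional[ECGSettings] = None) -> ECGTrace:
    """Dipole-source pseudo-ECG of a 1-D strand or 2-D sheet recording."""
    if isinstance(recording, SpaceTimeRecording):
        if settings is None:
            settings = default_strand_electrode(recording)
        x = (np.arange(recording.n_nodes) + 0.5) * recording.dx
        xe = settings.electrode_mm[0]
        ye, ze = settings.electrode_mm[1], settings.electrode_mm[2]
        if ye == 0.0 and ze == 0.0:
            if float(np.min(np.abs(xe - x))) < recording.dx:
                raise ValueError("electrode lies inside the tissue")
            terms = _gradient_terms_1d(recording.vm, x, xe)
            phi = settings.gain * terms.sum(axis=1) * recording.dx
        else:
            r = np.sqrt((xe - x) ** 2 + ye ** 2 + ze ** 2)
            if float(np.min(r)) < recording.dx:
                raise ValueError("electrode lies inside the tissue")
            dvdx = np.gradient(recording.vm, x, axis=1)
            geom = (xe - x) / r ** 3
            phi = settings.gain * ((-dvdx) * geom[None, :]).sum(axis=1) * recording.dx
        return ECGTrace(time=recording.time.copy(), phi=phi)

    if isinstance(recording, SheetRecording):
        if settings is None:
            raise ValueError("sheet recordings need explicit electrode settings")
        ny, nx = recording.vm.shape[1:]
        xs = (np.arange(nx) + 0.5) * recording.dx
        ys = (np.arange(ny) + 0.5) * recording.dx
        xe, ye, ze = settings.electrode_mm
        XX, YY = np.meshgrid(xs, ys)
        r = np.sqrt((xe - XX) ** 2 + (ye - YY) ** 2 + ze ** 2)
        if float(np.min(r[recording.mask])) < recording.dx:
            raise ValueError("electrode lies inside the tissue")
        vm = np.where(recording.mask[None, :, :], recording.vm,
                      np.nan)
        # gradients only inside the mask; treat mask edges as zero-flux
        vm_filled = np.where(np.isnan(vm), 0.0, vm)
        w = recording.mask.astype(float)
        dvdx = np.gradient(vm_filled, xs, axis=2) * w[None, :, :]
        dvdy = np.gradient(vm_filled, ys, axis=1) * w[None, :, :]
        gx = (xe - XX) / r ** 3
        gy = (ye - YY) / r ** 3
        phi = settings.gain * ((-dvdx) * gx + (-dvdy) * gy)
        phi = phi.reshape(phi.shape[0], -1).sum(axis=1) * recording.dx ** 2
        return ECGTrace(time=recording.time.copy(), phi=phi)

    raise TypeError(f"unsupported recording {type(recording).__name__}")


@dataclass
class QTResult:
    """QT interval and its endpoints (ms); flags mark detection failures."""

    qt: float
    qrs_onset: float
    t_end: float
    detected: bool = True

    def __post_init__(self) -> None:
        if self.detected and not self.qt > 0:
            raise ValueError("QT must be positive when detected")


def qt_interval(ecg: ECGTrace, stim_time: float = 0.0,
                onset_frac: float = 0.05, t_end_frac: float = 0.05,
                qrs_window: float = 100.0) -> QTResult:
    """Threshold-based QT measurement.

    QRS onset: first time after ``stim_time`` where |dφ/dt| exceeds
    ``onset_frac`` of its maximum.  T end: last time after the QRS window
    where |φ| stays at or above ``t_end_frac`` of the T-peak amplitude
    (tangent-free threshold method).
    """
    t = ecg.time
    phi = ecg.phi
    sel = t >= stim_time
    t = t[sel]
    phi = phi[sel]
    if len(t) < 3:
        raise ValueError("trace too short")
    dphi = np.abs(np.gradient(phi, t))
    peak_slope = float(np.max(dphi))
    amp = float(np.max(np.abs(phi)))
    if peak_slope <= 0 or amp <= 0:
        return QTResult(qt=float("nan"), qrs_onset=float("nan"),
                        t_end=float("nan"), detected=False)
    onset_idx = np.nonzero(dphi >= onset_frac * peak_slope)[0]
    qrs_onset = float(t[onset_idx[0]])
    after = t >= qrs_onset + qrs_window
    if not np.any(after):
        return QTResult(qt=float("nan"), qrs_onset=qrs_onset,
                        t_end=float("nan"), detected=False)
    t_peak_amp = float(np.max(np.abs(phi[after])))
    if t_peak_amp <= 0:
        return QTResult(qt=float("nan"), qrs_onset=qrs_onset,
                        t_end=float("nan"), detected=False)
    above = np.nonzero(after & (np.abs(phi) >= t_end_frac * t_peak_amp))[0]
    t_end = float(t[above[-1]])
    return QTResult(qt=t_end - qrs_onset, qrs_onset=qrs_onset, t_end=t_end)
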