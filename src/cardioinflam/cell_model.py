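"""Human ventricular myocyte model (ten Tusscher-Panfilov 2006 formulation).

Implements the three transmural variants (ENDO/MID/EPI) with full dynamic
intracellular Na+/K+/Ca2+ handling, exposed through parameter and state
dataclasses plus ``default_parameters`` / ``derivatives`` / ``step``.  The
parameter surface is what the :mod:`cardioinflam.inflammation` module
rescales or shifts: maximal conductances, SERCA uptake rate, SR leak rate,
and voltage offsets of the I_to inactivation and I_Kr activation steady
states.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import IO, Optional

import numpy as np

from . import _kernels as K


class Variant(str, Enum):
    """Transmural cell subtype."""

    ENDO = "ENDO"
    MID = "MID"
    EPI = "EPI"


class SolverInstabilityError(RuntimeError):
    """Raised when the integrator produces a non-finite or runaway value."""


@dataclass(frozen=True)
class CellParameters:
    """Maximal conductances, Ca-handling rates and gating-curve offsets.

    Conductances are in the units of the source model (nS/pF unless noted);
    ``v_max_up`` in mM/ms, ``v_leak``/``v_rel``/``v_xfer`` in 1/ms (flux rate
    constants), shifts in mV.  ``cm`` is the per-area membrane capacitance
    used by the monodomain equation (currents here are already per-pF, so cm
    only enters the tissue formulation symbolically).
    """

    variant: Variant = Variant.EPI
    g_na: float = 14.838
    g_cal: float = 0.0000398
    g_to: float = 0.294
    g_kr: float = 0.153
    g_ks: float = 0.392
    g_k1: float = 5.405
    g_pca: float = 0.1238
    g_pk: float = 0.0146
    g_bna: float = 0.00029
    g_bca: float = 0.000592
    k_naca: float = 1000.0
    p_nak: float = 2.724
    v_max_up: float = 0.006375
    v_leak: float = 0.00036
    v_rel: float = 0.102
    v_xfer: float = 0.0038
    cm: float = 1.0
    shift_ito_inact: float = 0.0
    shift_ikr_act: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "variant":
                continue
            if not math.isfinite(v):
                raise ValueError(f"non-finite parameter {f.name!r}")
            if f.name.startswith(("g_", "k_", "p_", "v_")) and v < 0:
                raise ValueError(f"negative conductance/rate {f.name!r} = {v}")

    def to_array(self) -> np.ndarray:
        """Flat parameter row consumed by the compiled kernels."""
        p = np.empty(K.N_PARAM)
        p[K.IP_GNA] = self.g_na
        p[K.IP_GCAL] = self.g_cal
        p[K.IP_GTO] = self.g_to
        p[K.IP_GKR] = self.g_kr
        p[K.IP_GKS] = self.g_ks
        p[K.IP_GK1] = self.g_k1
        p[K.IP_GPCA] = self.g_pca
        p[K.IP_GPK] = self.g_pk
        p[K.IP_GBNA] = self.g_bna
        p[K.IP_GBCA] = self.g_bca
        p[K.IP_KNACA] = self.k_naca
        p[K.IP_PNAK] = self.p_nak
        p[K.IP_VMAXUP] = self.v_max_up
        p[K.IP_VLEAK] = self.v_leak
        p[K.IP_VREL] = self.v_rel
        p[K.IP_VXFER] = self.v_xfer
        p[K.IP_SHIFT_S] = self.shift_ito_inact
        p[K.IP_SHIFT_XR1] = self.shift_ikr_act
        p[K.IP_ENDO_S] = 1.0 if self.variant == Variant.ENDO else 0.0
        return p

    def to_config(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["variant"] = self.variant.value
        return d

    @classmethod
    def from_config(cls, d: dict) -> "CellParameters":
        d = dict(d)
        d["variant"] = Variant(d["variant"])
        return cls(**d)

    def to_json(self, fp: IO[str]) -> None:
        json.dump(self.to_config(), fp, indent=2, sort_keys=True)


def default_parameters(variant: Variant | str) -> CellParameters:
    """Published baseline parameter set for a transmural variant.

    The transmural scheme of the source model assigns the MID cell a
    reduced slow delayed-rectifier conductance (long APD) and the ENDO cell
    a reduced transient-outward conductance plus its own I_to inactivation
    kinetics.
    """
    variant = Variant(variant)
    if variant == Variant.EPI:
        return CellParameters(variant=variant, g_to=0.294, g_ks=0.392)
    if variant == Variant.ENDO:
        return CellParameters(variant=variant, g_to=0.073, g_ks=0.392)
    if variant == Variant.MID:
        return CellParameters(variant=variant, g_to=0.294, g_ks=0.098)
    raise ValueError(f"unknown variant {variant!r}")


_GATE_FIELDS = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2", "f_cass")


@dataclass
class CellState:
    """Membrane voltage (mV), gates (dimensionless) and concentrations (mM)."""

    vm: float = -86.2
    m: float = 0.0
    h: float = 0.75
    j: float = 0.75
    xr1: float = 0.0
    xr2: float = 1.0
    xs: float = 0.0
    r: float = 0.0
    s: float = 1.0
    d: float = 0.0
    f: float = 1.0
    f2: float = 1.0
    f_cass: float = 1.0
    r_rel: float = 1.0
    ca_i: float = 0.00007
    ca_sr: float = 1.3
    ca_ss: float = 0.00007
    na_i: float = 7.67
    k_i: float = 138.3

    def to_array(self) -> np.ndarray:
        return np.array([self.vm, self.m, self.h, self.j, self.xr1, self.xr2,
                         self.xs, self.r, self.s, self.d, self.f, self.f2,
                         self.f_cass, self.r_rel, self.ca_i, self.ca_sr,
                         self.ca_ss, self.na_i, self.k_i])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "CellState":
        names = [f.name for f in fields(cls)]
        return cls(**{n: float(a[i]) for i, n in enumerate(names)})

    def validate(self) -> None:
        a = self.to_array()
        names = [f.name for f in fields(self)]
        for i, n in enumerate(names):
            if not math.isfinite(a[i]):
                raise SolverInstabilityError(f"non-finite state variable {n!r}")
        for g in _GATE_FIELDS + ("r_rel",):
            v = getattr(self, g)
            if not (0.0 <= v <= 1.0):
                raise SolverInstabilityError(f"gate {g!r} out of [0, 1]: {v}")
        for c in ("ca_i", "ca_sr", "ca_ss", "na_i", "k_i"):
            if getattr(self, c) <= 0:
                raise SolverInstabilityError(f"non-positive concentration {c!r}")

    @staticmethod
    def write_csv(states: "list[CellState]", fp: IO[str]) -> None:
        names = [f.name for f in fields(CellState)]
        w = csv.writer(fp)
        w.writerow(names)
        for s in states:
            w.writerow([repr(x) for x in s.to_array()])


@dataclass(frozen=True)
class CurrentSet:
    """Membrane currents (pA/pF) and SR calcium fluxes (mM/ms)."""

    i_na: float
    i_cal: float
    i_to: float
    i_kr: float
    i_ks: float
    i_k1: float
    i_naca: float
    i_nak: float
    i_pca: float
    i_pk: float
    i_bna: float
    i_bca: float
    j_up: float
    j_leak: float
    j_rel: float
    j_xfer: float

    @property
    def i_ion(self) -> float:
        """Total transmembrane ionic current (sum of membrane currents)."""
        return (self.i_na + self.i_cal + self.i_to + self.i_kr + self.i_ks
                + self.i_k1 + self.i_naca + self.i_nak + self.i_pca
                + self.i_pk + self.i_bna + self.i_bca)


def _rates(state: CellState, params: CellParameters, i_stim: float):
    S = state.to_array().reshape(1, -1)
    P = params.to_array().reshape(1, -1)
    ginf = np.empty(12)
    gtau = np.empty(12)
    cur = np.empty(K.N_CUR)
    dv, drq, dcai, dcasr, dcass, dnai, dki = K.node_rates(S, P, 0, i_stim, ginf, gtau, cur)
    return S, dv, drq, dcai, dcasr, dcass, dnai, dki, ginf, gtau, cur


def derivatives(state: CellState, params: CellParameters,
                i_stim: float = 0.0) -> tuple[CellState, CurrentSet]:
    """Time derivatives dState/dt and the instantaneous currents.

    ``i_stim`` is the depolarizing stimulus amplitude in pA/pF (stored
    positive; applied with depolarizing sign so that dVm/dt includes
    +i_stim).
    """
    arr = state.to_array()
    if not np.all(np.isfinite(arr)):
        raise SolverInstabilityError("non-finite value in input state")
    _, dv, drq, dcai, dcasr, dcass, dnai, dki, ginf, gtau, cur = _rates(state, params, i_stim)
    d = np.empty(K.N_STATE)
    d[K.SV_V] = dv + i_stim
    gates = arr[1:13]
    d[1:13] = (ginf - gates) / gtau
    d[K.SV_RQ] = drq
    d[K.SV_CAI] = dcai
    d[K.SV_CASR] = dcasr
    d[K.SV_CASS] = dcass
    d[K.SV_NAI] = dnai
    d[K.SV_KI] = dki
    currents = CurrentSet(*[float(c) for c in cur])
    return CellState.from_array(d), currents


def step(state: CellState, params: CellParameters, dt: float = 0.02,
         i_stim: float = 0.0) -> CellState:
    """One integration step: Rush-Larsen gates, forward Euler elsewhere.

    Raises :class:`SolverInstabilityError` naming the first offending
    variable if the result leaves its admissible range.
    """
    if not (0.0 < dt):
        raise ValueError("dt must be positive")
    S = state.to_array().reshape(1, -1)
    if not np.all(np.isfinite(S)):
        raise SolverInstabilityError("non-finite value in input state")
    P = params.to_array().reshape(1, -1)
    ginf = np.empty(12)
    gtau = np.empty(12)
    cur = np.empty(K.N_CUR)
    K.step_node(S, P, 0, i_stim, dt, ginf, gtau, cur)
    out = CellState.from_array(S[0])
    out.validate()
    return out


def resting_state(params: CellParameters, settle_ms: float = 10_000.0,
                  dt: float = 0.02) -> CellState:
    """State after ``settle_ms`` of quiescence (a numerical fixed point)."""
    S = CellState().to_array().reshape(1, -1)
    P = params.to_array().reshape(1, -1)
    T, vmin, idv = K.tables_for(dt)
    status, _, _ = K.run_cell_quiescent(S, P, dt, settle_ms, T, vmin, idv)
    if status != 0:
        raise SolverInstabilityError("instability while settling to rest")
    return CellState.from_array(S[0])


def resting_drift(params: CellParameters, duration_ms: float = 60_000.0,
                  dt: float = 0.02,
                  initial_state: Optional[CellState] = None) -> float:
    """Maximal |Vm - Vm(0)| (mV) over an unstimulated run."""
    state0 = initial_state if initial_state is not None else CellState()
    S = state0.to_array().reshape(1, -1)
    v0 = S[0, K.SV_V]
    P = params.to_array().reshape(1, -1)
    T, vmin, idv = K.tables_for(dt)
    status, vlo, vhi = K.run_cell_quiescent(S, P, dt, duration_ms, T, vmin, idv)
    if status != 0:
        raise SolverInstabilityError("instability during quiescent run")
    return max(abs(vlo - v0), abs(vhi - v0))


def perturbed(params: CellParameters, **changes) -> CellParameters:
    """Copy of ``params`` with the given fields replaced."""
    return replace(params, **changes)
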