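"""Cytokine channelopathy: experimentally reported effects and their composition.

Acute exposure (< 48 h) to the three major pro-inflammatory cytokines
TNF-α, IL-1β and IL-6 remodels ventricular electrophysiology through a
handful of targets: transient-outward (I_to) and rapid delayed-rectifier
(I_Kr) current densities and gating curves, L-type calcium current density,
SERCA expression (J_up) and SR calcium leak (J_leak).  This module encodes
the published effect sizes as data, composes any subset of cytokines into a
single multi-target perturbation at a chosen severity, and applies it to
cell parameters.

Severity semantics: the combined effect of several cytokines is taken as an
accumulation of the individual fractional changes; severity 1.0 is the
full reported ("inflammation") effect, 0.5 halves every reported effect
("mild inflammation"), 0 is the identity.  Tissue-level coupling loss is
carried alongside as a diffusion scale of 1 − 0.35·severity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, Mapping, Optional, Tuple

from .cell_model import CellParameters


class Cytokine(str, Enum):
    TNFA = "TNFa"
    IL1B = "IL1b"
    IL6 = "IL6"


class Target(str, Enum):
    ITO_DENSITY = "ITO_DENSITY"
    ITO_INACT_SHIFT = "ITO_INACT_SHIFT"
    IKR_DENSITY = "IKR_DENSITY"
    IKR_ACT_SHIFT = "IKR_ACT_SHIFT"
    ICAL_DENSITY = "ICAL_DENSITY"
    JUP_EXPRESSION = "JUP_EXPRESSION"
    JLEAK = "JLEAK"


#: targets expressed as a signed fractional change of a density/rate
FRACTION_TARGETS = frozenset({
    Target.ITO_DENSITY, Target.IKR_DENSITY, Target.ICAL_DENSITY,
    Target.JUP_EXPRESSION, Target.JLEAK,
})
#: targets expressed as a mV offset of a gating curve
SHIFT_TARGETS = frozenset({Target.ITO_INACT_SHIFT, Target.IKR_ACT_SHIFT})


@dataclass(frozen=True)
class CytokineEffect:
    """One experimentally reported cytokine→target effect.

    Exactly one of ``change_fraction`` (dimensionless signed fraction) and
    ``shift_mV`` is set.  ``change_fraction_range`` brackets the default
    when the source reported a range; the default is the range midpoint.
    """

    cytokine: Cytokine
    target: Target
    change_fraction: Optional[float] = None
    shift_mV: Optional[float] = None
    change_fraction_range: Optional[Tuple[float, float]] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if (self.change_fraction is None) == (self.shift_mV is None):
            raise ValueError("exactly one of change_fraction / shift_mV must be set")
        if self.change_fraction_range is not None:
            lo, hi = sorted(self.change_fraction_range)
            if not (lo <= self.change_fraction <= hi):
                raise ValueError("range does not bracket the default fraction")


def effect_table() -> list[CytokineEffect]:
    """The reported acute cytokine effects (treatment < 48 h).

    Ranged effects default to the range midpoint.  Negative shifts are
    leftward (toward more negative voltages).
    """
    return [
        CytokineEffect(Cytokine.TNFA, Target.ITO_DENSITY, change_fraction=-0.442,
                       change_fraction_range=(-0.65, -0.234),
                       provenance="I_to density -23.4..-65%, rat ventricular myocyte, 48 h"),
        CytokineEffect(Cytokine.TNFA, Target.ITO_INACT_SHIFT, shift_mV=-5.7,
                       provenance="I_to inactivation curve ~5.7 mV leftward, 48 h"),
        CytokineEffect(Cytokine.TNFA, Target.IKR_DENSITY, change_fraction=-0.33,
                       provenance="I_Kr density -33%, HEK293, 10 h"),
        CytokineEffect(Cytokine.IL6, Target.IKR_DENSITY, change_fraction=-0.296,
                       provenance="I_Kr density -29.6%, HEK293, 40 min"),
        CytokineEffect(Cytokine.IL6, Target.IKR_ACT_SHIFT, shift_mV=-5.0,
                       provenance="I_Kr activation curve 5 mV leftward, 40 min"),
        CytokineEffect(Cytokine.IL6, Target.ICAL_DENSITY, change_fraction=0.27,
                       provenance="I_CaL density +27%, mouse ventricular myocyte, 30 min"),
        CytokineEffect(Cytokine.IL6, Target.JUP_EXPRESSION, change_fraction=-0.355,
                       change_fraction_range=(-0.50, -0.21),
                       provenance="SERCA gene expression -21..-50%, rat, 48 h"),
        CytokineEffect(Cytokine.IL1B, Target.ITO_DENSITY, change_fraction=-0.368,
                       provenance="I_to density -36.8%, rat ventricular myocyte, 24 h"),
        CytokineEffect(Cytokine.IL1B, Target.JLEAK, change_fraction=0.636,
                       provenance="SR Ca2+ leak +63.6%, rat ventricular myocyte, 24 h"),
    ]


ALL_CYTOKINES = frozenset({Cytokine.TNFA, Cytokine.IL1B, Cytokine.IL6})

#: fractional reduction of tissue coupling at full severity
COUPLING_REDUCTION = 0.35


@dataclass(frozen=True)
class PerturbationSet:
    """A composed multi-target perturbation at a given severity.

    ``scale`` maps density/rate targets to multiplicative factors (>= 0),
    ``shift`` maps gating-curve targets to mV offsets.  ``diffusion_scale``
    is the factor on the tissue diffusion coefficient for 2-D use (1-D
    inflammatory segments override D directly instead).
    """

    scale: Mapping[Target, float] = field(default_factory=dict)
    shift: Mapping[Target, float] = field(default_factory=dict)
    severity: float = 0.0
    diffusion_scale: float = 1.0

    def scale_for(self, target: Target) -> float:
        return self.scale.get(target, 1.0)

    def shift_for(self, target: Target) -> float:
        return self.shift.get(target, 0.0)

    @property
    def is_identity(self) -> bool:
        return (all(v == 1.0 for v in self.scale.values())
                and all(v == 0.0 for v in self.shift.values())
                and self.diffusion_scale == 1.0)


IDENTITY = PerturbationSet()


def compose(cytokines: Iterable[Cytokine | str], severity: float,
            mode: str = "sum",
            overrides: Optional[Mapping[Target, float]] = None) -> PerturbationSet:
    """Compose per-cytokine effects into one perturbation.

    Per target, fractional changes from distinct cytokines are accumulated
    (``mode='sum'``: fractions summed then scaled by severity, the default;
    ``mode='product'``: per-cytokine factors ``1 + severity·f`` multiplied),
    and gating shifts are summed and scaled by severity.  Factors are
    floored at zero with a warning.  ``overrides`` replaces the default
    fractional change of a target before composition (e.g. to pick an
    endpoint of a reported range).
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    cyt = {Cytokine(c) for c in cytokines}
    if not cyt:
        raise ValueError("need a non-empty set of cytokines")
    if mode not in ("sum", "product"):
        raise ValueError(f"unknown composition mode {mode!r}")

    frac: Dict[Target, float] = {}
    fact: Dict[Target, float] = {}
    shift: Dict[Target, float] = {}
    for eff in effect_table():
        if eff.cytokine not in cyt:
            continue
        if eff.target in SHIFT_TARGETS:
            shift[eff.target] = shift.get(eff.target, 0.0) + severity * eff.shift_mV
        else:
            f = eff.change_fraction
            frac[eff.target] = frac.get(eff.target, 0.0) + f
            fact[eff.target] = fact.get(eff.target, 1.0) * (1.0 + severity * f)

    # overrides fix a target's *total* fractional change before severity
    if overrides:
        for t, f in overrides.items():
            t = Target(t)
            frac[t] = f
            fact[t] = 1.0 + severity * f

    scale: Dict[Target, float] = {}
    for t in frac:
        s = 1.0 + severity * frac[t] if mode == "sum" else fact[t]
        if s < 0.0:
            warnings.warn(f"perturbation factor for {t.value} floored at 0 "
                          f"(was {s:.3g})", stacklevel=2)
            s = 0.0
        scale[t] = s
    return PerturbationSet(scale=scale, shift=shift, severity=severity,
                           diffusion_scale=1.0 - COUPLING_REDUCTION * severity)


def apply_perturbation(params: CellParameters, p: PerturbationSet) -> CellParameters:
    """Rescaled/shifted copy of ``params``; the input is not mutated."""
    return replace(
        params,
        g_to=params.g_to * p.scale_for(Target.ITO_DENSITY),
        g_kr=params.g_kr * p.scale_for(Target.IKR_DENSITY),
        g_cal=params.g_cal * p.scale_for(Target.ICAL_DENSITY),
        v_max_up=params.v_max_up * p.scale_for(Target.JUP_EXPRESSION),
        v_leak=params.v_leak * p.scale_for(Target.JLEAK),
        shift_ito_inact=params.shift_ito_inact + p.shift_for(Target.ITO_INACT_SHIFT),
        shift_ikr_act=params.shift_ikr_act + p.shift_for(Target.IKR_ACT_SHIFT),
    )


def severity_preset(severity: float) -> PerturbationSet:
    """All three cytokines at the given severity (0 returns the identity)."""
    if severity == 0.0:
        return IDENTITY
    return compose(ALL_CYTOKINES, severity)
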