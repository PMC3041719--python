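"""Time-varying elastance chambers and diode valves.

Each chamber follows the classic elastance formulation: instantaneous
pressure is a time-varying stiffness applied to the volume above the
unstressed volume,

    E(t) = e_min + a(t) · (e_max_eff − e_min),      a(t) ∈ [0, 1]
    P(V, t) = E(t) · max(V − V0, 0)

where ``e_max_eff = (contractility/100) · e_max_ref`` — inotropy scales the
end-systolic elastance only, while the relaxed (diastolic) stiffness e_min
is a passive property.  The Frank-Starling behaviour of the whole model is
emergent: a larger end-diastolic volume meets the same end-systolic
elastance line, so the ejected volume grows with filling.

There is no suction: pressure is floored at zero below the unstressed
volume, consistent with a model that carries no blood inertia.

Valves are ideal diodes with a small series resistance: flow is
``max(ΔP, 0)/R``, strictly unidirectional, with no regurgitant or stenotic
states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import CardiolabError

#: activation rises for this fraction of systole, then falls
ACTIVATION_PEAK_FRACTION = 0.4


@dataclass
class ChamberSpec:
    """Elastance envelope plus this cycle's trigger window for one chamber."""

    e_min: float          # mmHg/ml
    e_max_ref: float      # mmHg/ml at 100 % inotropy
    v0: float             # ml
    contractility: float  # percent of reference inotropy
    onset: float = 0.0            # s within the cycle
    systole_duration: float = 0.3  # s

    @property
    def e_max_eff(self) -> float:
        return (self.contractility / 100.0) * self.e_max_ref


@dataclass
class ValveSpec:
    """Ideal diode valve between two compartments."""

    resistance: float   # mmHg·(ml/s)^-1
    upstream: str
    downstream: str

    def __post_init__(self):
        if self.resistance <= 0:
            raise CardiolabError("valve resistance must be > 0")


def activation(t_in_cycle: float, onset: float, duration: float) -> float:
    """Normalized contraction waveform a(t) ∈ [0, 1].

    Zero outside [onset, onset+duration]; inside, a two-phase raised
    cosine — rising over the first 40 % of systole to exactly 1, falling
    over the remaining 60 % — continuous everywhere, with a smooth peak of
    exactly 1 at onset + 0.4·duration.
    """
    if duration <= 0:
        raise ValueError("systole duration must be > 0")
    tau = t_in_cycle - onset
    if tau <= 0.0 or tau >= duration:
        return 0.0
    tau_peak = ACTIVATION_PEAK_FRACTION * duration
    if tau <= tau_peak:
        return 0.5 * (1.0 - math.cos(math.pi * tau / tau_peak))
    return 0.5 * (1.0 + math.cos(math.pi * (tau - tau_peak) / (duration - tau_peak)))


def chamber_pressure(spec: ChamberSpec, volume: float, act: float) -> float:
    """Instantaneous chamber pressure (mmHg) from volume and activation."""
    elastance = spec.e_min + act * (spec.e_max_eff - spec.e_min)
    stressed = volume - spec.v0
    return elastance * stressed if stressed > 0.0 else 0.0


def valve_flow(p_up: float, p_down: float, spec: ValveSpec) -> float:
    """Diode flow (ml/s): forward gradient divided by R, never negative."""
    dp = p_up - p_down
    return dp / spec.resistance if dp > 0.0 else 0.0
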