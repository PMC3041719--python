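"""Compartment networks and the discrete-time state update.

Two fixed topologies:

* **IHL** (isolated heart, 5 compartments): a constant-pressure venous
  source feeds the left atrium and ventricle, which eject into a two-stage
  arterial Windkessel (aorta + distal arterial bed) draining through the
  total peripheral resistance into a zero-pressure sink.  Preload is a
  boundary condition, so volume is not conserved — the source is unlimited.

* **CCL** (closed circulation loop, 10 compartments): systemic veins → RA →
  RV → pulmonary artery → pulmonary capillary bed → pulmonary veins → LA →
  LV → aorta → arterial bed → back to the systemic veins.  Every flow
  leaves one compartment and enters another, so total blood volume is
  conserved exactly, step by step, by construction.

The update is the classic recursive scheme: at each fixed 1 ms step all
pressures are computed from the current volumes, all flows from the
current pressures, and volumes are advanced explicitly (forward Euler).
No inertance elements exist anywhere in the network — blood mass is
neglected, as in the underlying teaching model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .ecg import TriggerSchedule
from .errors import ModelError, StabilityError
from .heart import ChamberSpec, activation, chamber_pressure
from .params import InternalConstants, Model, ParameterSet, validate

CHAMBER = "chamber"
VESSEL = "compliant_vessel"
SOURCE = "pressure_source"

#: pressure the open-ended IHL outflow drains into
SINK = None


@dataclass
class Compartment:
    id: str
    kind: str
    # chamber fields
    spec: ChamberSpec | None = None
    role: str | None = None          # 'atrial' | 'ventricular'
    enabled: bool = True             # False: contraction off (e_max_eff = e_min)
    # compliant_vessel fields
    compliance: float = 0.0          # ml/mmHg
    v_unstressed: float = 0.0        # ml
    # pressure_source field
    pressure: float = 0.0            # mmHg


@dataclass
class Connector:
    id: str
    kind: str                        # 'valve' | 'resistor'
    upstream: int                    # compartment index
    downstream: int | None           # compartment index or SINK
    resistance: float                # mmHg·(ml/s)^-1


@dataclass
class CirculationModel:
    model: Model
    compartments: list[Compartment]
    connectors: list[Connector]
    constants: InternalConstants

    def index(self, comp_id: str) -> int:
        for i, c in enumerate(self.compartments):
            if c.id == comp_id:
                return i
        raise KeyError(comp_id)

    def connector(self, conn_id: str) -> Connector:
        for c in self.connectors:
            if c.id == conn_id:
                return c
        raise KeyError(conn_id)

    @property
    def chambers(self) -> list[Compartment]:
        return [c for c in self.compartments if c.kind == CHAMBER]

    @property
    def valves(self) -> list[Connector]:
        return [c for c in self.connectors if c.kind == "valve"]


@dataclass
class CirculationState:
    """Snapshot of the network: volumes drive everything else."""

    t: float
    t_in_cycle: float
    volumes: list[float]             # ml, aligned with model.compartments
    pressures: list[float] = field(default_factory=list)   # mmHg
    flows: list[float] = field(default_factory=list)       # ml/s per connector

    def copy(self) -> "CirculationState":
        return replace(self, volumes=list(self.volumes),
                       pressures=list(self.pressures), flows=list(self.flows))

    def total_volume(self, model: CirculationModel) -> float:
        return sum(v for v, c in zip(self.volumes, model.compartments)
                   if c.kind != SOURCE)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _chamber(constants: InternalConstants, name: str, role: str,
             contractility: float) -> Compartment:
    ch = constants.chambers[name]
    spec = ChamberSpec(e_min=ch.e_min, e_max_ref=ch.e_max_ref, v0=ch.v0,
                       contractility=contractility)
    return Compartment(id=name, kind=CHAMBER, spec=spec, role=role)


def _vessel(constants: InternalConstants, name: str,
            compliance: float | None = None) -> Compartment:
    vs = constants.vessels[name]
    return Compartment(id=name, kind=VESSEL,
                       compliance=vs.compliance if compliance is None else compliance,
                       v_unstressed=vs.v_unstressed)


def build_ihl(params: ParameterSet,
              constants: InternalConstants | None = None) -> CirculationModel:
    """Isolated-heart network: 5 compartments, 2 valves, open outflow.

    The venous source holds the configured CVP; the aorta takes the
    user-facing compliance; the distal arterial bed drains through the TPR
    into a zero-pressure sink.
    """
    if Model(params.model) is not Model.IHL:
        raise ModelError(f"build_ihl requires model=IHL, got {params.model}")
    validate(params)
    constants = constants or InternalConstants()
    compartments = [
        Compartment(id="venous_source", kind=SOURCE, pressure=params.cvp),
        _chamber(constants, "la", "atrial", 100.0),
        _chamber(constants, "lv", "ventricular", params.contractility_lv),
        _vessel(constants, "aorta", compliance=params.compliance),
        _vessel(constants, "arteries"),
    ]
    connectors = [
        Connector("venous_inflow", "resistor", 0, 1, constants.r_venous_inflow),
        Connector("mitral_valve", "valve", 1, 2, constants.av_valve_resistance),
        Connector("aortic_valve", "valve", 2, 3, constants.valve_resistance),
        Connector("aorta_distal", "resistor", 3, 4, constants.r_aorta_distal),
        Connector("tpr", "resistor", 4, SINK, params.tpr),
    ]
    return CirculationModel(Model.IHL, compartments, connectors, constants)


def build_ccl(params: ParameterSet,
              constants: InternalConstants | None = None) -> CirculationModel:
    """Closed-loop network: 10 compartments in a volume-conserving ring.

    Four chambers and four valves; the TPR sits between the arterial bed
    and the systemic veins, the total lung resistance is split evenly
    across the pulmonary capillary bed.  Initial compartment volumes scale
    the configured volume distribution to the total blood volume.
    """
    if Model(params.model) is not Model.CCL:
        raise ModelError(f"build_ccl requires model=CCL, got {params.model}")
    validate(params)
    constants = constants or InternalConstants()
    compartments = [
        _vessel(constants, "systemic_veins"),
        _chamber(constants, "ra", "atrial", 100.0),
        _chamber(constants, "rv", "ventricular", params.contractility_rv),
        _vessel(constants, "pulmonary_artery"),
        _vessel(constants, "pulmonary_capillaries"),
        _vessel(constants, "pulmonary_veins"),
        _chamber(constants, "la", "atrial", 100.0),
        _chamber(constants, "lv", "ventricular", params.contractility_lv),
        _vessel(constants, "aorta", compliance=params.compliance),
        _vessel(constants, "arteries"),
    ]
    connectors = [
        Connector("vein_return", "resistor", 0, 1, constants.r_systemic_vein),
        Connector("tricuspid_valve", "valve", 1, 2, constants.av_valve_resistance),
        Connector("pulmonary_valve", "valve", 2, 3, constants.valve_resistance),
        Connector("tlr_proximal", "resistor", 3, 4, params.tlr / 2.0),
        Connector("tlr_distal", "resistor", 4, 5, params.tlr / 2.0),
        Connector("pulmonary_vein_return", "resistor", 5, 6, constants.r_pulmonary_vein),
        Connector("mitral_valve", "valve", 6, 7, constants.av_valve_resistance),
        Connector("aortic_valve", "valve", 7, 8, constants.valve_resistance),
        Connector("aorta_distal", "resistor", 8, 9, constants.r_aorta_distal),
        Connector("tpr", "resistor", 9, 0, params.tpr),
    ]
    return CirculationModel(Model.CCL, compartments, connectors, constants)


def initial_state(model: CirculationModel, params: ParameterSet) -> CirculationState:
    """Starting volumes: physiological filling, exact total in the loop."""
    constants = model.constants
    if model.model is Model.CCL:
        fractions = constants.initial_fractions()
        total_ml = params.blood_volume_ml
        volumes = [total_ml * fractions[c.id] for c in model.compartments]
    else:
        volumes = []
        for c in model.compartments:
            if c.kind == SOURCE:
                volumes.append(0.0)
            elif c.kind == CHAMBER:
                # relaxed chamber equilibrated to the preload pressure
                volumes.append(c.spec.v0 + params.cvp / c.spec.e_min)
            else:
                volumes.append(c.v_unstressed + 80.0 * c.compliance)
    state = CirculationState(t=0.0, t_in_cycle=0.0, volumes=volumes)
    state.pressures = _pressures(model, state, None)
    state.flows = [0.0] * len(model.connectors)
    return state


# ---------------------------------------------------------------------------
# The discrete-time update
# ---------------------------------------------------------------------------

def _chamber_activation(comp: Compartment, t_in_cycle: float,
                        triggers: TriggerSchedule | None) -> float:
    if triggers is None:
        return 0.0
    if comp.role == "atrial":
        return activation(t_in_cycle, triggers.atrial_onset,
                          triggers.systolic_duration_atrial)
    return activation(t_in_cycle, triggers.ventricular_onset,
                      triggers.systolic_duration_ventricular)


def _pressures(model: CirculationModel, state: CirculationState,
               triggers: TriggerSchedule | None) -> list[float]:
    pressures = []
    for comp, volume in zip(model.compartments, state.volumes):
        if comp.kind == CHAMBER:
            act = _chamber_activation(comp, state.t_in_cycle, triggers)
            if not comp.enabled:
                act = 0.0
            pressures.append(chamber_pressure(comp.spec, volume, act))
        elif comp.kind == VESSEL:
            stressed = volume - comp.v_unstressed
            pressures.append(stressed / comp.compliance if stressed > 0.0 else 0.0)
        else:
            pressures.append(comp.pressure)
    return pressures


def step(model: CirculationModel, state: CirculationState,
         triggers: TriggerSchedule | None, dt: float) -> CirculationState:
    """Advance the network by one explicit step of length ``dt``.

    Order of operations: activations from the trigger schedule at the
    current phase of the cycle → pressures from current volumes → flows
    from current pressures → volume update.  In the closed loop every flow
    moves volume between two compartments, so the total is conserved to
    floating-point rounding with no correction step.
    """
    pressures = _pressures(model, state, triggers)
    flows = []
    net = [0.0] * len(model.compartments)
    for conn in model.connectors:
        p_up = pressures[conn.upstream]
        p_down = 0.0 if conn.downstream is SINK else pressures[conn.downstream]
        if conn.kind == "valve":
            dp = p_up - p_down
            q = dp / conn.resistance if dp > 0.0 else 0.0
        else:
            q = (p_up - p_down) / conn.resistance
        flows.append(q)
        net[conn.upstream] -= q
        if conn.downstream is not SINK:
            net[conn.downstream] += q
    volumes = list(state.volumes)
    for i, comp in enumerate(model.compartments):
        if comp.kind == SOURCE:
            continue
        v = volumes[i] + dt * net[i]
        if v < 0.0:
            raise StabilityError(
                f"compartment {comp.id!r} volume went negative ({v:.3g} ml) "
                f"at t={state.t:.3f} s; use a smaller time step")
        volumes[i] = v
    return CirculationState(t=state.t + dt, t_in_cycle=state.t_in_cycle + dt,
                            volumes=volumes, pressures=pressures, flows=flows)


def build(params: ParameterSet,
          constants: InternalConstants | None = None) -> CirculationModel:
    """Dispatch to the builder matching ``params.model``."""
    if Model(params.model) is Model.IHL:
        return build_ihl(params, constants)
    return build_ccl(params, constants)
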