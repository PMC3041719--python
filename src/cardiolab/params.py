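"""User-facing physiological parameters and internal model constants.

The seven user-facing parameters (central venous pressure, heart rate,
left/right ventricular contractility, total peripheral resistance, aortic
compliance, total lung resistance, total blood volume) carry printed
defaults and hard min/max limits and are the only knobs a student of the
original teaching tool could turn.  Everything else the model needs —
chamber elastances, unstressed volumes, valve resistances, ECG timing
coefficients — lives in :class:`InternalConstants`, fixed in one place so
simulations are reproducible.

Out-of-range values are rejected, never clamped: a library cannot rely on
listbox widgets to make invalid input impossible, so it must say exactly
which field broke which bound.
"""

from __future__ import annotations

import dataclasses
import enum
import io
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigError, ValidationError


class Model(str, enum.Enum):
    """The two simulator configurations.

    IHL — isolated (left) heart: left atrium and ventricle fed by a
    constant-pressure venous source, ejecting into an open-ended arterial
    Windkessel.  CCL — closed circulation loop: all four chambers plus the
    systemic and pulmonary circulations in a volume-conserving ring.
    """

    IHL = "IHL"
    CCL = "CCL"


def _coerce_model(model) -> Model:
    if isinstance(model, Model):
        return model
    try:
        return Model(str(model).upper())
    except ValueError:
        valid = ", ".join(m.value for m in Model)
        raise ModelLookupError(
            f"unknown model {model!r}; valid models are: {valid}"
        ) from None


class ModelLookupError(ValidationError):
    """Raised for an unrecognised model selection."""

    def __init__(self, message: str):  # noqa: D107 - message-only variant
        Exception.__init__(self, message)
        self.violations = []


@dataclass(frozen=True)
class ParamInfo:
    """Limit-table row for one user-facing parameter."""

    name: str
    description: str
    default: float
    lo: float
    hi: float
    unit: str
    models: tuple[Model, ...]


#: The user-facing parameter table: defaults and closed min/max limits.
PARAMETER_TABLE: dict[str, ParamInfo] = {
    p.name: p
    for p in (
        ParamInfo("cvp", "Venous blood pressure in the vena cava",
                  10.0, 0.0, 30.0, "mmHg", (Model.IHL,)),
        ParamInfo("hr", "Heart rate",
                  70.0, 40.0, 160.0, "min^-1", (Model.IHL, Model.CCL)),
        ParamInfo("contractility_lv",
                  "Left-ventricular contractility relative to average inotropy",
                  100.0, 25.0, 200.0, "%", (Model.IHL, Model.CCL)),
        ParamInfo("contractility_rv",
                  "Right-ventricular contractility relative to average inotropy",
                  100.0, 25.0, 200.0, "%", (Model.CCL,)),
        ParamInfo("tpr", "Total peripheral resistance",
                  1.0, 0.2, 2.0, "mmHg (ml/s)^-1", (Model.IHL, Model.CCL)),
        ParamInfo("compliance", "Aortic wall compliance (dV/dP)",
                  1.5, 0.5, 2.0, "ml mmHg^-1", (Model.IHL, Model.CCL)),
        ParamInfo("tlr", "Total lung resistance",
                  0.1, 0.02, 0.5, "mmHg (ml/s)^-1", (Model.CCL,)),
        ParamInfo("blood_volume", "Total blood volume in the circulation",
                  5.2, 3.0, 6.4, "l", (Model.CCL,)),
    )
}


@dataclass(frozen=True)
class ParameterSet:
    """The complete user-facing parameter vector for one simulation.

    Units follow the limit table: pressures in mmHg, heart rate in min^-1,
    contractility in percent of reference inotropy, resistances in
    mmHg·(ml/s)^-1, compliance in ml·mmHg^-1, blood volume in litres.
    Fields not applicable to the chosen model (``cvp`` for the closed loop;
    ``tlr``, ``blood_volume``, ``contractility_rv`` for the isolated heart)
    are carried but ignored by the respective network builder.
    """

    model: Model = Model.CCL
    cvp: float = 10.0
    hr: float = 70.0
    contractility_lv: float = 100.0
    contractility_rv: float = 100.0
    tpr: float = 1.0
    compliance: float = 1.5
    tlr: float = 0.1
    blood_volume: float = 5.2

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields changed (not validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def blood_volume_ml(self) -> float:
        return self.blood_volume * 1000.0


def default_parameters(model) -> ParameterSet:
    """Return the printed default parameter set for a model.

    Raises a rejection naming the valid models for an unknown selection.
    """
    model = _coerce_model(model)
    return ParameterSet(
        model=model,
        **{name: info.default for name, info in PARAMETER_TABLE.items()},
    )


def validate(params: ParameterSet) -> ParameterSet:
    """Check every field against its closed limit interval.

    Returns the input unchanged (no clamping) if all fields are in range;
    otherwise raises :class:`ValidationError` listing *every* violating
    field with its bound.  Idempotent by construction.
    """
    _coerce_model(params.model)
    violations = []
    for name, info in PARAMETER_TABLE.items():
        value = getattr(params, name)
        if not (info.lo <= value <= info.hi):
            violations.append((name, value, (info.lo, info.hi), info.unit))
    if violations:
        raise ValidationError(violations)
    return params


# ---------------------------------------------------------------------------
# Internal constants (not user-facing; fixed for reproducibility)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChamberConstants:
    """Elastance envelope of one chamber: E(t) sweeps e_min → e_max_ref·c%."""

    e_min: float        # mmHg/ml, diastolic (relaxed) elastance
    e_max_ref: float    # mmHg/ml, end-systolic elastance at 100 % inotropy
    v0: float           # ml, unstressed volume (zero-pressure intercept)


@dataclass(frozen=True)
class VesselConstants:
    """Linear compliant reservoir: P = (V − V_unstressed)/C, floored at 0."""

    compliance: float     # ml/mmHg
    v_unstressed: float   # ml


@dataclass(frozen=True)
class InternalConstants:
    """Model constants below the user-facing surface.

    Human-calibrated values chosen once so that the all-default steady state
    lands in textbook adult ranges (aortic pressure near 120/80 mmHg,
    cardiac output 4–6 l/min) — see docs/methods.md for the calibration
    rationale.  All elastances in mmHg/ml, volumes in ml, resistances in
    mmHg·(ml/s)^-1, compliances in ml/mmHg, times in seconds.
    """

    chambers: Mapping[str, ChamberConstants] = field(default_factory=lambda: {
        "lv": ChamberConstants(e_min=0.08, e_max_ref=2.5, v0=10.0),
        "rv": ChamberConstants(e_min=0.04, e_max_ref=0.6, v0=10.0),
        "la": ChamberConstants(e_min=0.12, e_max_ref=0.17, v0=5.0),
        "ra": ChamberConstants(e_min=0.12, e_max_ref=0.17, v0=5.0),
    })
    vessels: Mapping[str, VesselConstants] = field(default_factory=lambda: {
        # the aorta's compliance is replaced by the user parameter at build
        "aorta": VesselConstants(compliance=1.5, v_unstressed=60.0),
        "arteries": VesselConstants(compliance=0.3, v_unstressed=380.0),
        "systemic_veins": VesselConstants(compliance=60.0, v_unstressed=3030.0),
        "pulmonary_artery": VesselConstants(compliance=4.0, v_unstressed=40.0),
        "pulmonary_capillaries": VesselConstants(compliance=5.0, v_unstressed=120.0),
        "pulmonary_veins": VesselConstants(compliance=15.0, v_unstressed=380.0),
    })
    #: semilunar (outflow) valves: low series resistance
    valve_resistance: float = 0.005
    #: atrioventricular (inflow) valves: higher effective resistance, the
    #: rate-limiting element of passive ventricular filling — this is what
    #: makes diastolic filling (and the atrial kick's value) rate-dependent
    av_valve_resistance: float = 0.015
    r_venous_inflow: float = 0.005     # IHL source → left atrium
    r_aorta_distal: float = 0.08       # aorta → distal arterial bed
    r_systemic_vein: float = 0.003     # systemic veins → right atrium
    r_pulmonary_vein: float = 0.003    # pulmonary veins → left atrium
    electromechanical_delay: float = 0.02
    dt: float = 0.001
    #: quadratic interval coefficients (a, b, c): X(rr) = a + b·rr + c·rr²
    ecg_coefficients: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "p_dur": (0.07, 0.02, 0.0),
            "pr": (0.10, 0.06, 0.0),
            "qrs": (0.09, 0.0, 0.0),
            "qt": (0.086667, 0.402222, -0.088889),
        })
    #: target closed-loop volume distribution (ml at the 5.2 l reference);
    #: initial volumes scale these to the configured total blood volume
    ccl_volume_distribution: Mapping[str, float] = field(default_factory=lambda: {
        "systemic_veins": 3428.6,
        "ra": 60.0,
        "rv": 120.0,
        "pulmonary_artery": 100.0,
        "pulmonary_capillaries": 180.0,
        "pulmonary_veins": 530.0,
        "la": 60.0,
        "lv": 120.0,
        "aorta": 195.0,
        "arteries": 406.4,
    })
    f_long: float = 0.60  # longitudinal share of LV volume change (AVPD)

    def initial_fractions(self) -> dict[str, float]:
        """Closed-loop initial volume fractions (sum to 1 within 1e-9)."""
        total = sum(self.ccl_volume_distribution.values())
        return {k: v / total for k, v in self.ccl_volume_distribution.items()}

    def __post_init__(self):
        for name, ch in self.chambers.items():
            if not (ch.e_min > 0 and ch.e_max_ref > 0 and ch.v0 >= 0):
                raise ConfigError(f"chamber {name!r}: elastances must be > 0, v0 >= 0")
        for name, vs in self.vessels.items():
            if not (vs.compliance > 0 and vs.v_unstressed >= 0):
                raise ConfigError(f"vessel {name!r}: compliance must be > 0")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if abs(sum(self.initial_fractions().values()) - 1.0) > 1e-9:
            raise ConfigError("initial volume fractions must sum to 1")


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

_CONFIG_KEYS = ("model",) + tuple(PARAMETER_TABLE)


def serialize(params: ParameterSet) -> str:
    """Render a parameter set as a YAML document (round-trips exactly)."""
    data = {"model": params.model.value}
    data.update({name: getattr(params, name) for name in PARAMETER_TABLE})
    return yaml.safe_dump(data, sort_keys=False)


def save_config(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize(params))


def load_config(path) -> tuple[ParameterSet, InternalConstants]:
    """Load a YAML/JSON parameter file; unset keys fall back to defaults.

    The file may contain only the keys ``model, cvp, hr, contractility_lv,
    contractility_rv, tpr, compliance, tlr, blood_volume``.  The result is
    validated; internal constants are always the shipped defaults.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(data).__name__}")
    unknown = set(data) - set(_CONFIG_KEYS)
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; allowed: {list(_CONFIG_KEYS)}")
    model = _coerce_model(data.pop("model", Model.CCL))
    params = default_parameters(model)
    numeric = {}
    for key, value in data.items():
        if not isinstance(value, (int, float)):
            raise ConfigError(f"config key {key!r} must be numeric, got {value!r}")
        numeric[key] = float(value)
    params = params.replace(**numeric)
    return validate(params), InternalConstants()
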