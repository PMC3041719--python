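"""The 1 ms time loop: runs, live parameter changes, steady state, sweeps.

The whole simulator is deterministic and seed-free: identical inputs give
bit-identical traces.  The engine advances the network in fixed 1 ms steps
(the constants' ``dt``), cycle by cycle.  At each cycle boundary the
current heart rate is turned into an ECG interval set and a mechanical
trigger schedule; heart-rate changes requested mid-cycle therefore take
effect at the next cycle start, so the electrical cycle is never torn.
All other parameters apply at the very next step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import circulation
from .circulation import CHAMBER, SINK, SOURCE, CirculationModel
from .ecg import timing_for_rate, trigger_schedule, validate_coefficients, waveform
from .errors import ConvergenceError, ValidationError
from .params import (InternalConstants, Model, PARAMETER_TABLE, ParameterSet,
                     validate)


@dataclass(frozen=True)
class RunSettings:
    """Run-length and bookkeeping controls (not physiology)."""

    duration: float = 30.0         # s
    record_every: int = 1          # record one row every k steps
    steady_state_tol: float = 0.1  # ml cycle-to-cycle EDV change
    max_cycles: int = 300

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class Trace:
    """Recorded time series of a run, one row per recorded step."""

    data: pd.DataFrame
    params: ParameterSet
    constants: InternalConstants
    dt: float

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6g")

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()


class Simulation:
    """A live run: step through cycles, change parameters on the fly.

    This is the API analogue of the original tool's interactive panel —
    parameter changes "run immediately into the model's calculations"
    without resetting the state.
    """

    def __init__(self, model: CirculationModel, params: ParameterSet,
                 settings: RunSettings | None = None):
        validate(params)
        validate_coefficients(model.constants.ecg_coefficients,
                              model.constants.electromechanical_delay)
        self.model = model
        self.params = params
        self.settings = settings or RunSettings()
        self.constants = model.constants
        self.dt = self.constants.dt
        self.state = circulation.initial_state(model, params)
        self.cycle_index = 0           # completed cycles
        self.cycle_stats: list[dict] = []
        self._pending_hr: float | None = None
        self._hr = params.hr
        self._steps_recorded = 0
        self._step_counter = 0
        self._columns = self._column_names()
        self._rows: dict[str, list[float]] = {c: [] for c in self._columns}
        self._begin_cycle()

    # -- bookkeeping ------------------------------------------------------

    def _column_names(self) -> list[str]:
        cols = ["time_s"]
        for c in self.model.compartments:
            if c.kind != SOURCE:
                cols.append(f"{c.id}_volume_ml")
        for c in self.model.compartments:
            cols.append(f"{c.id}_pressure_mmHg")
        for conn in self.model.connectors:
            cols.append(f"{conn.id}_flow_ml_s")
        cols.append("ecg_au")
        return cols

    def _begin_cycle(self) -> None:
        if self._pending_hr is not None:
            self._hr = self._pending_hr
            self._pending_hr = None
        delay = self.constants.electromechanical_delay
        self.timing = timing_for_rate(self._hr, self.constants.ecg_coefficients,
                                      delay)
        self.triggers = trigger_schedule(self.timing, delay)
        self._n_cycle = int(round(self.timing.rr / self.dt))
        self._step_in_cycle = 0
        self._ecg = waveform(self.timing, np.arange(self._n_cycle) * self.dt)
        self._stats = {"edv_lv": -np.inf, "esv_lv": np.inf,
                       "edv_rv": -np.inf, "esv_rv": np.inf,
                       "psys": -np.inf, "pdia": np.inf, "hr": self._hr}
        self._i_lv = self.model.index("lv")
        self._i_rv = (self.model.index("rv")
                      if self.model.model is Model.CCL else None)
        self._i_ao = self.model.index("aorta")

    def _end_cycle(self) -> None:
        self.cycle_stats.append(dict(self._stats))
        self.cycle_index += 1
        self.state.t_in_cycle = 0.0
        self._begin_cycle()

    # -- stepping ---------------------------------------------------------

    def advance(self, n_steps: int, record: bool = True) -> None:
        """Run ``n_steps`` explicit steps, rolling over cycle boundaries."""
        rows = self._rows
        every = self.settings.record_every
        for _ in range(n_steps):
            if self._step_in_cycle >= self._n_cycle:
                self._end_cycle()
            prev = self.state
            self.state = circulation.step(self.model, prev, self.triggers, self.dt)
            ecg_val = float(self._ecg[self._step_in_cycle])
            st = self._stats
            v_lv = prev.volumes[self._i_lv]
            if v_lv > st["edv_lv"]:
                st["edv_lv"] = v_lv
            if v_lv < st["esv_lv"]:
                st["esv_lv"] = v_lv
            if self._i_rv is not None:
                v_rv = prev.volumes[self._i_rv]
                if v_rv > st["edv_rv"]:
                    st["edv_rv"] = v_rv
                if v_rv < st["esv_rv"]:
                    st["esv_rv"] = v_rv
            p_ao = self.state.pressures[self._i_ao]
            if p_ao > st["psys"]:
                st["psys"] = p_ao
            if p_ao < st["pdia"]:
                st["pdia"] = p_ao
            if record and self._step_counter % every == 0:
                it = iter(self._columns)
                rows[next(it)].append(prev.t)
                for i, c in enumerate(self.model.compartments):
                    if c.kind != SOURCE:
                        rows[next(it)].append(prev.volumes[i])
                for i in range(len(self.model.compartments)):
                    rows[next(it)].append(self.state.pressures[i])
                for j in range(len(self.model.connectors)):
                    rows[next(it)].append(self.state.flows[j])
                rows[next(it)].append(ecg_val)
            self._step_counter += 1
            self._step_in_cycle += 1

    def advance_cycle(self, record: bool = True) -> dict:
        """Run exactly one full cardiac cycle; return its summary stats."""
        if self._step_in_cycle >= self._n_cycle:
            self._end_cycle()
        self.advance(self._n_cycle - self._step_in_cycle, record=record)
        self._end_cycle()
        return self.cycle_stats[-1]

    # -- live parameter changes ------------------------------------------

    def set_parameter(self, name: str, value: float) -> None:
        """Apply a user-parameter change to the running model.

        The state (volumes) is never reset.  Heart-rate changes defer to
        the next cycle boundary; a blood-volume change rescales all
        compartment volumes proportionally so the loop total matches the
        new setting; everything else takes effect at the next step.
        """
        info = PARAMETER_TABLE.get(name)
        if info is None:
            raise KeyError(f"unknown parameter {name!r}; "
                           f"valid: {sorted(PARAMETER_TABLE)}")
        if self.model.model not in info.models:
            raise KeyError(f"parameter {name!r} is not applicable to "
                           f"the {self.model.model.value} model")
        value = float(value)
        if not (info.lo <= value <= info.hi):
            raise ValidationError([(name, value, (info.lo, info.hi), info.unit)])
        if name == "hr":
            self._pending_hr = value
        elif name == "cvp":
            self.model.compartments[self.model.index("venous_source")].pressure = value
        elif name == "contractility_lv":
            self.model.compartments[self._i_lv].spec.contractility = value
        elif name == "contractility_rv":
            self.model.compartments[self._i_rv].spec.contractility = value
        elif name == "tpr":
            self.model.connector("tpr").resistance = value
        elif name == "compliance":
            self.model.compartments[self._i_ao].compliance = value
        elif name == "tlr":
            self.model.connector("tlr_proximal").resistance = value / 2.0
            self.model.connector("tlr_distal").resistance = value / 2.0
        elif name == "blood_volume":
            total = self.state.total_volume(self.model)
            scale = value * 1000.0 / total
            self.state.volumes = [v * scale for v in self.state.volumes]
        self.params = self.params.replace(**{name: value})

    # -- results ----------------------------------------------------------

    def trace(self) -> Trace:
        data = pd.DataFrame({c: np.asarray(v) for c, v in self._rows.items()})
        return Trace(data=data, params=self.params, constants=self.constants,
                     dt=self.dt)


# ---------------------------------------------------------------------------
# High-level runners
# ---------------------------------------------------------------------------

def run(model: CirculationModel, params: ParameterSet,
        settings: RunSettings | None = None) -> Trace:
    """Run for a fixed duration and return the recorded trace."""
    settings = settings or RunSettings()
    sim = Simulation(model, params, settings)
    n = int(round(settings.duration / sim.dt))
    sim.advance(n)
    return sim.trace()


def run_to_steady_state(model: CirculationModel, params: ParameterSet,
                        settings: RunSettings | None = None,
                        record: bool = True) -> tuple[Trace, int]:
    """Run whole cycles until the end-diastolic volume stops changing.

    Convergence at the first cycle k (1-based) where the cycle-to-cycle
    EDV change of the left ventricle (and the right one, in the closed
    loop) drops below ``steady_state_tol``.  EDV is used because it is the
    slowest-settling state of a compliant loop.
    """
    settings = settings or RunSettings()
    if settings.max_cycles < 3:
        raise ValueError("max_cycles must be >= 3")
    sim = Simulation(model, params, settings)
    both = sim.model.model is Model.CCL
    prev = None
    for k in range(1, settings.max_cycles + 1):
        stats = sim.advance_cycle(record=record)
        if prev is not None:
            delta = abs(stats["edv_lv"] - prev["edv_lv"])
            if both:
                delta = max(delta, abs(stats["edv_rv"] - prev["edv_rv"]))
            if delta < settings.steady_state_tol:
                return sim.trace(), k
        prev = stats
    raise ConvergenceError(
        f"no steady state within {settings.max_cycles} cycles; "
        f"last EDV delta {delta:.3g} ml")


def sweep(params: ParameterSet, sweep_param: str, values,
          metrics_names=("edv_ml", "esv_ml", "sv_ml", "co_ml_min", "ef",
                         "psys_mmHg", "pdia_mmHg", "pulse_pressure_mmHg", "dhf"),
          settings: RunSettings | None = None) -> pd.DataFrame:
    """Steady-state metrics versus one swept parameter.

    Each point is computed from a fresh run (no hysteresis).  Returns a
    DataFrame whose first column is the swept parameter.
    """
    from . import metrics as metrics_mod
    settings = settings or RunSettings()
    info = PARAMETER_TABLE.get(sweep_param)
    if info is None:
        raise KeyError(f"unknown sweep parameter {sweep_param!r}")
    rows = []
    for value in values:
        p = validate(params.replace(**{sweep_param: float(value)}))
        model = circulation.build(p)
        trace, _ = run_to_steady_state(model, p, settings)
        summary = metrics_mod.cycle_metrics(trace, p.hr, allow_zero_stroke=True)
        row = {sweep_param: float(value)}
        row.update({name: getattr(summary, name) for name in metrics_names})
        rows.append(row)
    return pd.DataFrame(rows)
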