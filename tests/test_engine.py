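"""Time loop determinism, steady-state detection, live changes, sweeps."""

import dataclasses

import numpy as np
import pytest

import cardiolab as cl
from cardiolab.errors import ValidationError


class TestRun:
    def test_one_second_run_records_thousand_steps(self, ihl_params):
        trace = cl.run(cl.build(ihl_params), ihl_params,
                       cl.RunSettings(duration=1.0))
        assert len(trace) == 1000
        dt = np.diff(trace.column("time_s"))
        assert np.allclose(dt, 0.001)

    def test_record_every_thins_the_trace(self, ihl_params):
        trace = cl.run(cl.build(ihl_params), ihl_params,
                       cl.RunSettings(duration=1.0, record_every=10))
        assert len(trace) == 100

    def test_identical_inputs_give_bitwise_identical_traces(self, ccl_params):
        t1 = cl.run(cl.build(ccl_params), ccl_params, cl.RunSettings(duration=2.0))
        t2 = cl.run(cl.build(ccl_params), ccl_params, cl.RunSettings(duration=2.0))
        assert t1.data.equals(t2.data)

    def test_trace_columns_cover_topology_with_unit_suffixes(self, ccl_params):
        trace = cl.run(cl.build(ccl_params), ccl_params, cl.RunSettings(duration=0.1))
        cols = set(trace.data.columns)
        assert "time_s" in cols and "ecg_au" in cols
        assert "lv_volume_ml" in cols and "aorta_pressure_mmHg" in cols
        assert "mitral_valve_flow_ml_s" in cols
        assert len([c for c in cols if c.endswith("_volume_ml")]) == 10

    def test_trace_csv_round_trip(self, ihl_params, tmp_path):
        import pandas as pd
        trace = cl.run(cl.build(ihl_params), ihl_params, cl.RunSettings(duration=0.2))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = pd.read_csv(path)
        assert list(back.columns) == list(trace.data.columns)
        assert len(back) == len(trace)


class TestSteadyState:
    def test_ihl_defaults_converge_quickly(self, ihl_params):
        model = cl.build(ihl_params)
        _, k = cl.run_to_steady_state(model, ihl_params)
        assert k <= 30

    def test_infinite_tolerance_returns_second_cycle(self, ihl_params):
        model = cl.build(ihl_params)
        settings = cl.RunSettings(steady_state_tol=float("inf"))
        _, k = cl.run_to_steady_state(model, ihl_params, settings)
        assert k == 2

    def test_ccl_edv_stays_settled_after_convergence(self, ccl_params):
        model = cl.build(ccl_params)
        _, k = cl.run_to_steady_state(model, ccl_params)
        sim = cl.Simulation(cl.build(ccl_params), ccl_params)
        for _ in range(k + 10):
            sim.advance_cycle(record=False)
        edvs = [s["edv_lv"] for s in sim.cycle_stats[k - 1:]]
        deltas = [abs(b - a) for a, b in zip(edvs, edvs[1:])]
        assert max(deltas) < 0.1

    def test_unreachable_tolerance_raises_convergence_error(self, ccl_params):
        model = cl.build(ccl_params)
        settings = cl.RunSettings(steady_state_tol=0.0, max_cycles=5)
        with pytest.raises(cl.ConvergenceError, match="EDV"):
            cl.run_to_steady_state(model, ccl_params, settings)


class TestSetParameter:
    def test_unknown_name_rejected(self, ihl_params):
        sim = cl.Simulation(cl.build(ihl_params), ihl_params)
        with pytest.raises(KeyError, match="unknown parameter"):
            sim.set_parameter("afterload", 1.0)

    def test_parameter_not_applicable_to_model_rejected(self, ccl_params):
        sim = cl.Simulation(cl.build(ccl_params), ccl_params)
        with pytest.raises(KeyError, match="not applicable"):
            sim.set_parameter("cvp", 5.0)

    def test_out_of_range_value_rejected(self, ihl_params):
        sim = cl.Simulation(cl.build(ihl_params), ihl_params)
        with pytest.raises(ValidationError, match="hr"):
            sim.set_parameter("hr", 200.0)

    def test_raising_tpr_raises_aortic_pressure(self, ihl_params):
        sim = cl.Simulation(cl.build(ihl_params), ihl_params)
        for _ in range(15):
            sim.advance_cycle(record=False)
        before = sim.cycle_stats[-1]["psys"]
        sim.set_parameter("tpr", 2.0)
        for _ in range(15):
            sim.advance_cycle(record=False)
        after = sim.cycle_stats[-1]["psys"]
        assert after > before + 10.0

    def test_setting_identical_value_is_a_bitwise_noop(self, ihl_params):
        s1 = cl.Simulation(cl.build(ihl_params), ihl_params)
        s1.advance(2000)
        s2 = cl.Simulation(cl.build(ihl_params), ihl_params)
        s2.advance(1000)
        s2.set_parameter("tpr", ihl_params.tpr)
        s2.advance(1000)
        assert s1.trace().data.equals(s2.trace().data)

    def test_hr_change_defers_to_next_cycle_boundary(self, ihl_params):
        sim = cl.Simulation(cl.build(ihl_params), ihl_params)
        sim.advance(100)
        sim.set_parameter("hr", 120.0)
        assert sim.timing.rr == pytest.approx(60.0 / 70.0)  # current cycle intact
        sim.advance_cycle()
        assert sim.timing.rr == pytest.approx(0.5)

    def test_midrun_change_conserves_loop_volume(self, ccl_params):
        sim = cl.Simulation(cl.build(ccl_params), ccl_params)
        sim.advance(500, record=False)
        sim.set_parameter("tpr", 1.8)
        sim.set_parameter("contractility_lv", 150.0)
        sim.advance(500, record=False)
        assert sim.state.total_volume(sim.model) == pytest.approx(5200.0, abs=1e-6)

    def test_blood_volume_change_rescales_to_new_total(self, ccl_params):
        sim = cl.Simulation(cl.build(ccl_params), ccl_params)
        sim.advance(500, record=False)
        sim.set_parameter("blood_volume", 4.0)
        assert sim.state.total_volume(sim.model) == pytest.approx(4000.0, abs=1e-6)
        sim.advance(500, record=False)
        assert sim.state.total_volume(sim.model) == pytest.approx(4000.0, abs=1e-6)


class TestSweep:
    def test_single_value_sweep_matches_direct_steady_state(self, ihl_params):
        table = cl.sweep(ihl_params, "hr", [70.0])
        direct = cl.steady_state_metrics(ihl_params)
        assert len(table) == 1
        assert table.loc[0, "hr"] == 70.0
        assert table.loc[0, "sv_ml"] == pytest.approx(direct.sv_ml)
        assert table.loc[0, "co_ml_min"] == pytest.approx(direct.co_ml_min)

    def test_sweep_param_is_first_column(self, ihl_params):
        table = cl.sweep(ihl_params, "cvp", [5.0, 10.0], metrics_names=("sv_ml",))
        assert list(table.columns)[0] == "cvp"

    def test_out_of_range_sweep_value_rejected(self, ihl_params):
        with pytest.raises(ValidationError):
            cl.sweep(ihl_params, "hr", [170.0])


def test_halving_dt_barely_changes_stroke_volume(ihl_params):
    """Discretization check: the 1 ms step is not driving the physiology."""
    sv = {}
    for dt in (0.001, 0.0005):
        constants = dataclasses.replace(cl.InternalConstants(), dt=dt)
        sv[dt] = cl.steady_state_metrics(ihl_params, constants).sv_ml
    assert abs(sv[0.001] - sv[0.0005]) / sv[0.0005] < 0.01
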