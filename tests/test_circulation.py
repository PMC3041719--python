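"""Network construction and the discrete-time update."""

import math

import pytest

import cardiolab as cl
from cardiolab.circulation import (CHAMBER, SINK, SOURCE, VESSEL, Compartment,
                                   Connector, CirculationModel,
                                   CirculationState, build_ccl, build_ihl,
                                   initial_state, step)
from cardiolab.errors import ModelError, StabilityError
from cardiolab.params import InternalConstants, Model


class TestBuildIhl:
    def test_exactly_five_compartments(self, ihl_params):
        model = build_ihl(ihl_params)
        assert len(model.compartments) == 5

    def test_two_valves_mitral_and_aortic(self, ihl_params):
        model = build_ihl(ihl_params)
        assert {v.id for v in model.valves} == {"mitral_valve", "aortic_valve"}

    def test_aorta_takes_user_compliance(self, ihl_params):
        model = build_ihl(ihl_params.replace(compliance=0.7))
        aorta = model.compartments[model.index("aorta")]
        assert aorta.compliance == 0.7

    def test_source_holds_cvp_and_outflow_is_open(self, ihl_params):
        model = build_ihl(ihl_params.replace(cvp=17.0))
        source = model.compartments[model.index("venous_source")]
        assert source.kind == SOURCE and source.pressure == 17.0
        tpr = model.connector("tpr")
        assert tpr.downstream is SINK and tpr.resistance == ihl_params.tpr

    def test_wrong_model_rejected(self, ccl_params):
        with pytest.raises(ModelError):
            build_ihl(ccl_params)


class TestBuildCcl:
    def test_exactly_ten_compartments(self, ccl_params):
        model = build_ccl(ccl_params)
        assert len(model.compartments) == 10
        assert not any(c.kind == SOURCE for c in model.compartments)

    def test_four_valves(self, ccl_params):
        model = build_ccl(ccl_params)
        assert {v.id for v in model.valves} == {
            "tricuspid_valve", "pulmonary_valve", "mitral_valve", "aortic_valve"}

    def test_initial_volumes_sum_to_blood_volume(self, ccl_params):
        model = build_ccl(ccl_params)
        state = initial_state(model, ccl_params)
        assert state.total_volume(model) == pytest.approx(5200.0, abs=1e-9)
        small = ccl_params.replace(blood_volume=3.0)
        state = initial_state(build_ccl(small), small)
        assert state.total_volume(model) == pytest.approx(3000.0, abs=1e-9)

    def test_loop_is_closed(self, ccl_params):
        model = build_ccl(ccl_params)
        assert all(c.downstream is not SINK for c in model.connectors)
        # every compartment has at least one inflow and one outflow
        ups = {c.upstream for c in model.connectors}
        downs = {c.downstream for c in model.connectors}
        assert ups == downs == set(range(10))

    def test_tlr_split_across_capillary_bed(self, ccl_params):
        model = build_ccl(ccl_params.replace(tlr=0.4))
        assert model.connector("tlr_proximal").resistance == pytest.approx(0.2)
        assert model.connector("tlr_distal").resistance == pytest.approx(0.2)

    def test_wrong_model_rejected(self, ihl_params):
        with pytest.raises(ModelError):
            build_ccl(ihl_params)


class TestStep:
    def test_zero_gradients_leave_state_unchanged(self, ihl_params):
        # empty heart at zero preload: every pressure 0, every flow 0
        params = ihl_params.replace(cvp=0.0)
        model = build_ihl(params)
        state = initial_state(model, params)
        for i, comp in enumerate(model.compartments):
            if comp.kind == CHAMBER:
                state.volumes[i] = comp.spec.v0
            elif comp.kind == VESSEL:
                state.volumes[i] = comp.v_unstressed
        nxt = step(model, state, None, 0.001)
        assert nxt.volumes == state.volumes
        assert nxt.t == pytest.approx(state.t + 0.001)
        assert all(q == 0.0 for q in nxt.flows)

    def test_single_step_conserves_closed_loop_volume_exactly(self, ccl_params):
        model = build_ccl(ccl_params)
        state = initial_state(model, ccl_params)
        before = state.total_volume(model)
        for _ in range(50):
            state = step(model, state, None, 0.001)
        assert state.total_volume(model) == pytest.approx(before, abs=1e-9)

    def test_negative_volume_raises_stability_error(self):
        # pathological: tiny compliance + tiny resistance drains the
        # compartment by more than its content in one step
        tank = Compartment(id="tank", kind=VESSEL, compliance=0.001,
                           v_unstressed=0.0)
        drain = Connector("drain", "resistor", 0, SINK, 0.001)
        model = CirculationModel(Model.IHL, [tank], [drain],
                                 InternalConstants())
        state = CirculationState(t=0.0, t_in_cycle=0.0, volumes=[1.0])
        with pytest.raises(StabilityError, match="smaller time step"):
            step(model, state, None, 0.001)


class TestRcDecayOracle:
    """Discrete update versus the closed-form Windkessel discharge.

    A single compliant compartment draining through a resistor is the
    textbook RC circuit: P(t) = P0·exp(−t/(R·C)).  The 1 ms explicit
    update must track the exponential within 0.5 % over one time constant.
    """

    def test_pressure_decay_matches_exponential(self):
        R, C, P0 = 1.0, 1.5, 100.0
        tank = Compartment(id="tank", kind=VESSEL, compliance=C,
                           v_unstressed=0.0)
        drain = Connector("drain", "resistor", 0, SINK, R)
        model = CirculationModel(Model.IHL, [tank], [drain],
                                 InternalConstants())
        state = CirculationState(t=0.0, t_in_cycle=0.0, volumes=[P0 * C])
        dt, tau = 0.001, R * C
        n = int(round(tau / dt))
        worst = 0.0
        for k in range(1, n + 1):
            state = step(model, state, None, dt)
            p_discrete = state.volumes[0] / C
            p_exact = P0 * math.exp(-k * dt / tau)
            worst = max(worst, abs(p_discrete - p_exact) / p_exact)
        assert worst < 0.005


def test_valve_flows_never_negative_in_default_runs(ihl_steady_trace,
                                                    ccl_steady_trace):
    for trace in (ihl_steady_trace, ccl_steady_trace):
        for col in trace.data.columns:
            if col.endswith("_valve_flow_ml_s"):
                assert (trace.data[col] >= 0.0).all(), col


def test_aortic_valve_closed_during_diastole(ihl_steady_trace):
    # whenever LV pressure is below aortic pressure, aortic flow is zero
    data = ihl_steady_trace.data
    closed = data["lv_pressure_mmHg"] <= data["aorta_pressure_mmHg"]
    assert (data.loc[closed, "aortic_valve_flow_ml_s"] == 0.0).all()
    # and the valve does open during systole
    assert data["aortic_valve_flow_ml_s"].max() > 0.0
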