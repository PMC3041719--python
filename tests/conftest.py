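import pytest

import cardiolab as cl


@pytest.fixture(scope="session")
def ihl_params():
    return cl.default_parameters(cl.Model.IHL)


@pytest.fixture(scope="session")
def ccl_params():
    return cl.default_parameters(cl.Model.CCL)


@pytest.fixture(scope="session")
def ihl_steady_trace(ihl_params):
    """Steady-state IHL trace at defaults, shared across tests."""
    model = cl.build(ihl_params)
    trace, _ = cl.run_to_steady_state(model, ihl_params)
    return trace


@pytest.fixture(scope="session")
def ccl_steady_trace(ccl_params):
    """Steady-state CCL trace at defaults, shared across tests."""
    model = cl.build(ccl_params)
    trace, _ = cl.run_to_steady_state(model, ccl_params)
    return trace
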