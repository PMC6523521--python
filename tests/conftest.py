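import pytest

from ecgcea import load_parameters, run_base_case


@pytest.fixture(scope="session")
def params():
    """Built-in default parameter set (shared; treat as read-only)."""
    return load_parameters(None)


@pytest.fixture(scope="session")
def base_1y(params):
    return run_base_case(params, horizon_years=1.0)


@pytest.fixture(scope="session")
def base_40y(params):
    return run_base_case(params)
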