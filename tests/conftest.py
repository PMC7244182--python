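import pytest
from hypothesis import HealthCheck, settings

import tricomplete as tc

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def equilateral():
    return tc.TriangleTemplate.from_angles("eq", (60, 60, 60), side_c=10, handedness="left")


@pytest.fixture
def exp1_design():
    return tc.exp1_design(seed=0)


@pytest.fixture
def exp2_design():
    return tc.exp2_design(seed=0)


@pytest.fixture
def make_session(exp1_design):
    """Factory: simulated exp1 session from a given model/params/seed."""

    def _make(params, seed=0, subject_id="S01"):
        session = tc.build_session(exp1_design, seed=seed, subject_id=subject_id)
        return tc.simulate_responses(session, params, seed=seed + 1)

    return _make
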