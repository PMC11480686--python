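import numpy as np
import pytest

import omhcsim as om
from omhcsim.outcomes import calibrate, replication_targets


@pytest.fixture(scope="session")
def profile():
    return om.default_profile()


@pytest.fixture(scope="session")
def calib_params(profile):
    return calibrate(replication_targets(), profile, n_sim=20_000, rng=7)


@pytest.fixture
def seeker_factory():
    counter = [0]

    def make(arrival_minute=0, gender="female", birth_year=1990,
             topic="depression", patience=5, id=None):
        counter[0] += 1
        return om.SeekerAgent(
            id=id or f"s{counter[0]}",
            arrival_minute=arrival_minute,
            gender=gender,
            birth_year=birth_year,
            topic=topic,
            patience=patience,
        )

    return make


@pytest.fixture
def counselor_factory():
    counter = [0]

    def make(arrival_minute=0, gender="female", birth_year=1990,
             topics=("depression",), decision_delay=0.0, idle_timeout=100,
             arrival_phase=0.0, id=None):
        counter[0] += 1
        return om.CounselorAgent(
            id=id or f"c{counter[0]}",
            arrival_minute=arrival_minute,
            gender=gender,
            birth_year=birth_year,
            topics=tuple(topics),
            decision_delay=decision_delay,
            idle_timeout=idle_timeout,
            arrival_phase=arrival_phase,
        )

    return make


@pytest.fixture(scope="session")
def run_short(profile, calib_params):
    """Factory for short simulation runs sharing the calibrated outcome model."""

    def make(policy="replication", seed=0, horizon=1500, profile=profile, **kw):
        policy_spec = policy if isinstance(policy, om.PolicySpec) else om.PolicySpec(policy)
        cfg = om.SimulationConfig(
            policy=policy_spec, profile=profile, outcome_params=calib_params,
            horizon_minutes=horizon, seed=seed, **kw,
        )
        return om.run(cfg)

    return make
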