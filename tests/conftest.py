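import numpy as np
import pytest

from whistlecee.synthetic import SimConfig, simulate_cee


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def control_cee():
    """One simulated control experiment with the default study conditions."""
    return simulate_cee(SimConfig(cee_id="ctl", cee_type="control", seed=11))


@pytest.fixture(scope="session")
def mfas_cee():
    """One simulated sonar experiment with a strong 5-s post-ping response."""
    return simulate_cee(
        SimConfig(
            cee_id="mfa", cee_type="mfas", seed=12, response_fold=15.0,
            suppress_during_ping=True, rl_max_db=152.0,
        )
    )
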