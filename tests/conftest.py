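import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psnav.experiments import scaled_plan, train

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TRAIN_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def scaled_policies():
    """Policies trained under the desk-scale protocol, one per seed.

    Shared across the suite because each training run costs tens of
    seconds; the policies are treated as frozen afterwards.
    """
    out = {}
    for seed in TRAIN_SEEDS:
        plan = scaled_plan(seed=seed)
        out[seed] = (train(plan).policy, plan)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
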