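import numpy as np
import pytest

from relapsekit import decision, synth


@pytest.fixture(scope="session")
def schedule():
    return decision.build_task_schedule(seed=42)


@pytest.fixture(scope="session")
def default_cfg():
    return synth.default_config()


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic study shared across tests (default group sizes)."""
    return synth.generate_dataset(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
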