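import numpy as np
import pytest

from pebga import TABLE1_QLR, TaskConfig, simulate_patient


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig(n_sessions=3)


@pytest.fixture(scope="session")
def simulated_patient(task_config):
    """Three QLr sessions at the published group-mean parameters."""
    return simulate_patient(TABLE1_QLR, task_config, np.random.default_rng(1234))
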