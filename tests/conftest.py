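import numpy as np
import pandas as pd
import pytest

from flankerddm import GROUP_PARAMS, GeneratorSpec, generate_behavior, \
    generate_task_design, simulate_trials


@pytest.fixture(scope="session")
def group_params():
    return GROUP_PARAMS


@pytest.fixture(scope="session")
def behavior_1088():
    """One participant's worth of generated behaviour (default spec)."""
    design = generate_task_design(1088, seed=11)
    return generate_behavior(design, GeneratorSpec(seed=42))


@pytest.fixture(scope="session")
def sim_5000(group_params):
    """5000 simulated trials at group parameters with recorded internals."""
    design = pd.DataFrame({"congruent": np.arange(5000) % 2 == 0})
    return simulate_trials(group_params, design, seed=7)
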