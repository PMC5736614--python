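import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle modules

from feedlearn.task_engine import SQUARES, TaskConfig, run_session


class RandomPolicy:
    """Uniform random chooser with an omission probability; history-blind."""

    def __init__(self, p_too_late: float = 0.0):
        self.p_too_late = p_too_late

    def __call__(self, stimulus_id, history, rng):
        if self.p_too_late > 0 and rng.random() < self.p_too_late:
            return None
        return int(rng.integers(len(SQUARES)))


def random_session(rng, n_sequences=1, p_too_late=0.0, use_agent=False):
    """One random session (a single sequence stays within 12 trials)."""
    if use_agent:
        from feedlearn.agents import AgentParams, make_policy

        params = AgentParams(
            p_use_positive=float(rng.uniform(0.2, 1.0)),
            p_use_negative=float(rng.uniform(0.2, 1.0)),
            p_elim_memory=float(rng.uniform(0.0, 1.0)),
            p_too_late=p_too_late,
        )
        policy = make_policy(params)
    else:
        policy = RandomPolicy(p_too_late)
    config = TaskConfig(n_sequences=n_sequences, seed=int(rng.integers(2**31)))
    return run_session(policy, config, rng)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
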