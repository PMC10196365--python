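import numpy as np
import pytest

from predinf import (
    ObserverConfig,
    TaskConfig,
    build_trial_table,
    generate_session,
    run_conditioned,
    run_ideal_observer,
    session_from_runs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def task_cfg():
    return TaskConfig()


@pytest.fixture
def obs_cfg():
    return ObserverConfig()


@pytest.fixture
def session_runs(task_cfg):
    """One default task session (4 runs x 70 trials), fixed seed."""
    return generate_session(task_cfg, np.random.default_rng(7))


@pytest.fixture
def ideal_trial_table(session_runs, obs_cfg):
    """Trial table of a noise-free ideal observer on the fixture session."""
    preds = run_ideal_observer(session_runs, obs_cfg)
    session = session_from_runs("ideal", session_runs, preds)
    trajectory = run_conditioned(preds, session_runs, obs_cfg)
    return build_trial_table(session, session_runs, trajectory)
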