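import pytest

from passdyn.simulate import run_session
from passdyn.task import build_task_space


@pytest.fixture(scope="session")
def task():
    return build_task_space()


@pytest.fixture(scope="session")
def default_session():
    """One default-parameter session, near-target release strategy."""
    return run_session(seed=1, pass_strategy="near_target")


@pytest.fixture(scope="session")
def confed_session():
    """One default-parameter session, near-confederate release strategy."""
    return run_session(seed=2, pass_strategy="near_confederate")
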