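import numpy as np
import pytest

from stopsig.cohort import SubjectParams
from stopsig.task import TaskConfig


@pytest.fixture
def subject() -> SubjectParams:
    """Default-parameter control subject (deterministic lapse-free variant
    is built per test where needed)."""
    return SubjectParams("sub-test01", "control", 30.0)


@pytest.fixture
def clean_subject() -> SubjectParams:
    """Subject without lapses or key errors, for race-logic tests."""
    return SubjectParams("sub-test02", "control", 30.0,
                         go_error_rate=0.0, go_miss_rate=0.0)


@pytest.fixture
def tiny_task() -> TaskConfig:
    return TaskConfig(n_runs=1, blocks_per_run=1, go_per_block=6,
                      stop_per_block=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
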