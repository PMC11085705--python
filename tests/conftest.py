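import numpy as np
import pytest

from somhebb import (
    CLASS_SUBSETS,
    GestureClass,
    TrainingSchedule,
    default_signatures,
    generate_dataset,
)


@pytest.fixture(scope="session")
def signatures():
    return default_signatures()


@pytest.fixture(scope="session")
def two_class_segments():
    """Small labeled dataset shared by the slower end-to-end tests."""
    return generate_dataset(CLASS_SUBSETS[2], 10, seed=42)


@pytest.fixture
def fast_schedule():
    """Short schedule for tests that only need a structurally trained map."""
    return TrainingSchedule(epochs=15, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def all_classes():
    return tuple(GestureClass)
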