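import numpy as np
import pytest

from ppfc import (
    HistoryFunctions,
    compute_bounds,
    evaluate_H1_H10,
    example1_initial_data,
    example1_model,
)


@pytest.fixture(scope="session")
def example1():
    return example1_model()


@pytest.fixture(scope="session")
def example1_bounds(example1):
    return compute_bounds(example1)


@pytest.fixture(scope="session")
def example1_criteria(example1):
    crits, bounds = evaluate_H1_H10(example1)
    return crits


@pytest.fixture(scope="session")
def example1_init():
    return example1_initial_data()


@pytest.fixture
def unit_history():
    return HistoryFunctions.constant([1.0] * 8)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
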