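import hypothesis
import pytest

from comdiss.datasets import (
    load_dissolution_runs,
    load_energies,
    load_inhibition_points,
    load_inhibition_table,
)

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def dissolution_runs():
    """(control, additive) reference dissolution runs."""
    return load_dissolution_runs()


@pytest.fixture(scope="session")
def inhibition():
    """(R0, inhibition points) reference series."""
    return load_inhibition_points()


@pytest.fixture(scope="session")
def inhibition_df():
    return load_inhibition_table()


@pytest.fixture(scope="session")
def energies():
    return load_energies()
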