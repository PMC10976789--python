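import warnings

import pytest
from hypothesis import HealthCheck, settings

from vhabpcea import BoundsAnomalyWarning, paper_fixture

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.filter_too_much, HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_params():
    """The built-in base case (published input-table values)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BoundsAnomalyWarning)
        return paper_fixture()


@pytest.fixture()
def params(base_params):
    """A mutable deep copy of the base case for per-test perturbation."""
    return base_params.model_copy(deep=True)
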