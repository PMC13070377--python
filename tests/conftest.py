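import numpy as np
import pytest

from besurv.config import default_spec
from besurv.synthetic import fixture_table4


@pytest.fixture(scope="session")
def spec():
    """The shipped model configuration (calibrated natural history,
    documented placeholder costs/utilities)."""
    return default_spec()


@pytest.fixture(scope="session")
def table4_counts():
    """Observed per-group event/exposure totals from the surveillance cohort."""
    return fixture_table4()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
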