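import numpy as np
import pytest

from pmtox import default_cohort_spec, generate_quant_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_quant_cohort(default_cohort_spec(11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
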