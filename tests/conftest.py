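import numpy as np
import pytest

import irregular_af as ia


@pytest.fixture(scope="session")
def rr_cohort():
    """Default RR-level cohort: 50 strips per rhythm class, seed 42."""
    return ia.simulate_rr_cohort(50, 42)


@pytest.fixture(scope="session")
def ecg_cohort():
    """Default ECG cohort: 50 records per rhythm class, seed 42."""
    return ia.simulate_cohort(50, 42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
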