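import numpy as np
import pytest

from crosscal.synthetic import default_codam_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One realized default cohort (n=550, four analytes), shared read-only."""
    return generate_cohort(default_codam_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
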