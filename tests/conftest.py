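import numpy as np
import pytest

from bardex import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded cohort at study-default composition (61 patients, 90 bars)."""
    cfg = SyntheticCohortConfig(seed=7)
    patients, bars, labels = generate_cohort(cfg)
    return cfg, patients, bars, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(20160119)
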