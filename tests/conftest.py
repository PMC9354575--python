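import numpy as np
import pytest

from precision_bench import (
    estimate_biological_effects,
    estimate_handling_effects,
    generate_paired_study,
)
from precision_bench.synthetic import default_fixture


@pytest.fixture(scope="session")
def default_study():
    """Desk-scale paired study (48 samples, 120 probes x 3 replicates)."""
    study, truth = generate_paired_study(default_fixture())
    return study, truth


@pytest.fixture(scope="session")
def bio(default_study):
    study, _ = default_study
    return estimate_biological_effects(study)


@pytest.fixture(scope="session")
def handling(default_study):
    study, _ = default_study
    return estimate_handling_effects(study)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
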