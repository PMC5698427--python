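import numpy as np
import pytest

from cinp import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Planted expression design with no replicate noise (exact fold changes)."""
    return synthgen.generate_expression_dataset(
        synthgen.default_design(noise_cv=0.0), seed=11
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Synthetic cohort with a planted log-hazard ratio of 0.7."""
    return synthgen.generate_survival_cohort(
        synthgen.SyntheticCohortSpec(n_patients=600, beta=0.7, seed=5)
    )
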