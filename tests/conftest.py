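import numpy as np
import pytest

from griefnet.synthetic import (
    CohortConfig,
    generate_instrument_cohort,
    generate_true_network,
    inject_missingness,
)


@pytest.fixture(scope="session")
def true_network():
    """Sparse 13-node ground truth in the density-0.5 regime."""
    return generate_true_network(13, 0.5, -0.04, 0.49, seed=7)


@pytest.fixture(scope="session")
def cohort():
    """Complete synthetic cohort of 92 participants."""
    return generate_instrument_cohort(92, CohortConfig(), seed=3)


@pytest.fixture(scope="session")
def incomplete_cohort(cohort):
    """Cohort with per-scale missingness in the study's reported range."""
    items = inject_missingness(
        cohort.items, {"TGI": 0.008, "CAPS": 0.057, "COPISAC": 0.03}, seed=5
    )
    return items, cohort.loss_metadata
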