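import numpy as np
import pandas as pd
import pytest

from hefi_cvd import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small confounded cohort with the default protective effect."""
    return generate_cohort(GeneratorConfig(n_participants=800, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """Medium cohort reused by the heavier model-fitting tests."""
    return generate_cohort(GeneratorConfig(n_participants=4000, seed=11))
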