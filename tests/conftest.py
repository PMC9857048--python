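import numpy as np
import pandas as pd
import pytest

from psmalesion import (
    SyntheticCohortConfig,
    classify_table,
    generate_cohort,
    synthetic_reference_cohort,
)


@pytest.fixture(scope="session")
def reference_classified() -> pd.DataFrame:
    """The synthetic per-lesion expansion of the published counts, classified."""
    lesions, references = synthetic_reference_cohort()
    classified, excluded = classify_table(lesions, references)
    assert len(excluded) == 0
    return classified


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort (12 patients) plus its classified table."""
    config = SyntheticCohortConfig(n_patients=12, seed=7)
    lesions, references = generate_cohort(config)
    classified, _ = classify_table(lesions, references)
    return config, lesions, references, classified


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
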