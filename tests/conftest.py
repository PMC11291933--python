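import logging

import numpy as np
import pandas as pd
import pytest

from deconfound.cohort import (CohortSpec, CovariateSpec,
                               generate_metadata)
from deconfound.tables import FeatureTable

logging.getLogger("deconfound").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def reference_metadata() -> pd.DataFrame:
    """15 controls / 22 mild / 8 severe, two samples per subject."""
    return generate_metadata(CohortSpec(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


@pytest.fixture()
def small_counts_table(rng) -> FeatureTable:
    """20 samples x 12 features of random counts."""
    data = pd.DataFrame(
        rng.integers(0, 200, size=(20, 12)),
        index=[f"s{i:02d}" for i in range(20)],
        columns=[f"f{j:02d}" for j in range(12)],
    )
    return FeatureTable(data, space="gut_taxa", state="counts")


def two_group_metadata(seed: int = 0, n_mild: int = 22, n_severe: int = 23,
                       coupling: float = 0.625) -> pd.DataFrame:
    """Patients-only cohort with an antibiotics covariate coupled to
    severity at a pinned point-biserial of about 0.5."""
    covs = (CovariateSpec("antibiotics", "binary", strength=coupling,
                          base=0.2, zero_in_controls=True,
                          exact_counts=True),)
    return generate_metadata(CohortSpec(n_controls=0, n_mild=n_mild,
                                        n_severe=n_severe, covariates=covs,
                                        seed=seed))
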