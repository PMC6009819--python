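import warnings

import numpy as np
import pandas as pd
import pytest

from tagdnl.containers import FeatureTable
from tagdnl.preprocess import qc_normalize
from tagdnl.synthetic import CohortSpec, generate_cohort

warnings.filterwarnings("ignore", message="Maximum Likelihood optimization")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused across tests (250 subjects, 5 plates)."""
    return generate_cohort(CohortSpec(n_subjects=250, n_plates=5, seed=11))


@pytest.fixture(scope="session")
def normed_small_cohort(small_cohort):
    table, subjects = small_cohort
    normed, report = qc_normalize(table)
    return normed, subjects, report


@pytest.fixture(scope="session")
def default_cohort():
    """Full default-scale cohort (1507 subjects, 19 plates)."""
    return generate_cohort(CohortSpec(seed=1))


def tiny_table(values, plates, qc_flags, columns=None):
    """Small hand-built FeatureTable for arithmetic examples."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    columns = columns or [f"TAG(5{i}:1)" for i in range(values.shape[1])]
    idx = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    return FeatureTable(
        pd.DataFrame(values, index=idx, columns=columns),
        pd.Series(list(plates), index=idx),
        pd.Series(list(qc_flags), index=idx),
    )
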