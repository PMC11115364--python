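import numpy as np
import pytest

import riskshift as rs


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with its ground truth (session-cached)."""
    table, truth = rs.generate_cohort(rs.CohortConfig(n_per_group=20), ("PR", "RP"), seed=1)
    return table, truth


@pytest.fixture(scope="session")
def small_kept(small_cohort):
    table, _ = small_cohort
    kept, report = rs.apply_exclusions(table)
    return kept, report
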