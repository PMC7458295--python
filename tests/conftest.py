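import numpy as np
import pytest

import sgaskit as sk


@pytest.fixture(scope="session")
def cohort_10k():
    """Reference-conditions cohort reused across read-only tests."""
    return sk.simulate_cohort(sk.CohortConfig(n_births=10_000, seed=42))


@pytest.fixture(scope="session")
def eligible_1wk(cohort_10k):
    return sk.filter_eligible(cohort_10k, 1)


@pytest.fixture(scope="session")
def totals(eligible_1wk):
    a1 = np.array([r.items_a1.total() for r in eligible_1wk])
    a2 = np.array([r.items_a2.total() for r in eligible_1wk])
    return a1, a2
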