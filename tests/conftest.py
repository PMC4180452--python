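import numpy as np
import pytest

import gompertzle as gle
from gompertzle.published import GROUP_COUNTS, N_GROUPS


@pytest.fixture(scope="session")
def ref_model():
    """Shared-shape model reconstructed from the published quantile table."""
    return gle.reference_model()


@pytest.fixture(scope="session")
def dev_probs():
    counts = np.array(GROUP_COUNTS["development"], dtype=float)
    return tuple(counts / counts.sum())


@pytest.fixture(scope="session")
def sim_cohort(dev_probs):
    """One medium synthetic cohort (n=4000) with published-table truth."""
    spec = gle.CohortSpec(n=4000, group_probabilities=dev_probs, horizon=10.0)
    return gle.sample_cohort(spec, seed=42)


@pytest.fixture(scope="session")
def sim_fit(sim_cohort):
    return gle.fit_mle(sim_cohort, family="gompertz")


@pytest.fixture()
def all_groups():
    return list(range(N_GROUPS))
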