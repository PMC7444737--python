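import numpy as np
import pytest

import parcelclass as pc


@pytest.fixture(scope="session")
def mc_cohort():
    """Monte-Carlo cohort: delta = 0.3 planted on parcel 5 against 10 targets."""
    cfg = pc.CohortConfig(
        n_subjects=200, n_parcels=30, n_volumes=300, seed=42,
        effect_parcels={5: 0.3},
    )
    return pc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def mc_connectomes(mc_cohort):
    return pc.cohort_connectomes(mc_cohort)


@pytest.fixture(scope="session")
def mc_zstack(mc_connectomes):
    return pc.stack_connectomes(mc_connectomes)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort with one strongly informative parcel (delta = 0.5 on parcel 3)."""
    cfg = pc.CohortConfig(
        n_subjects=40, n_parcels=8, n_volumes=120, seed=7,
        effect_parcels={3: 0.5},
    )
    return pc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_zstack(small_cohort):
    return pc.stack_connectomes(pc.cohort_connectomes(small_cohort))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
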