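import numpy as np
import pytest

from mammocad import PhantomSpec, extract_dataset, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def phantom_default():
    return generate_phantom(PhantomSpec(rng_seed=0))


@pytest.fixture(scope="session")
def cohort_100():
    """50 normal + 50 abnormal phantoms at the default study conditions."""
    return generate_cohort(50, 50, rng_seed=0)


@pytest.fixture(scope="session")
def features_100(cohort_100):
    return extract_dataset(
        [t.image for t in cohort_100], [t.class_label for t in cohort_100]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
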