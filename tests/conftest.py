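import numpy as np
import pytest

from dtboundary import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact imbalanced cohort with 4 informative + 8 noise features."""
    return generate_cohort(
        CohortSpec(n_hc=120, n_mci=50, n_ad=30, d_noise=8, seed=7)
    )


@pytest.fixture(scope="session")
def hc_matrix(small_cohort):
    """Normalized healthy-control block of the small cohort."""
    from dtboundary import apply_minmax, fit_minmax

    hc = small_cohort.X[small_cohort.labels == "HC"]
    return apply_minmax(fit_minmax(hc), hc)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
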