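import numpy as np
import pytest

from dimbrain.synthetic import CohortConfig, efa_regime_config, make_cohort


@pytest.fixture(scope="session")
def ica_cohort():
    """Study-scale cohort in the independence regime (3 exponential latents,
    hierarchical items); half-sample ICA stability needs this n."""
    return make_cohort(CohortConfig(n=2000, n_items=119, n_features=16, n_sites=8, seed=31))


@pytest.fixture(scope="session")
def efa_cohort():
    """Correlated-latent cohort (pairwise 0.6, Gaussian copula, no
    sub-syndrome splitting) for the factor-analysis pipeline."""
    return make_cohort(efa_regime_config(n=2000, n_items=60, n_features=16, n_sites=8, seed=37))


@pytest.fixture(scope="session")
def efa_poly(efa_cohort):
    """Polychoric matrix of the EFA cohort, shared across tests."""
    from dimbrain.efa import polychoric_matrix

    return polychoric_matrix(efa_cohort.ratings)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
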