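import numpy as np
import pandas as pd
import pytest

from cfrna.synthetic import default_config, make_reference, simulate_cohort


@pytest.fixture(scope="session")
def reference():
    return make_reference(8, 1500, seed=7)


@pytest.fixture(scope="session")
def small_cohort(reference):
    """Two-group cohort with planted signal, shared across fast tests."""
    cfg = default_config(
        group_sizes={"KD": 24, "healthy": 24},
        n_genes=1500,
        signature_size=40,
        shared_signature_size=20,
        signature_log2fc=1.5,
        seed=7,
    )
    return simulate_cohort(cfg, reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def nb_counts(rng, mu, phi, n):
    """NB draws (variance mu + phi mu^2) as a genes x samples array."""
    mu = np.asarray(mu, dtype=float)[:, None] * np.ones((1, n))
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[:, None], mu.shape)
    lam = rng.gamma(1.0 / phi, mu * phi)
    return rng.poisson(lam).astype(np.int64)


@pytest.fixture()
def nb_sim():
    return nb_counts
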