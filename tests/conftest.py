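import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import capescan as cs

settings.register_profile(
    "ci", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null_cohort():
    """Default-structure synthetic cohort with no planted genetics."""
    config = cs.SimulationConfig(n_individuals=416, n_markers=50, seed=11)
    genotypes, traits = cs.simulate_cohort(config)
    return config, genotypes, traits


@pytest.fixture()
def dominant_matrix():
    """Small complete dominant-coded genotype matrix."""
    rng = np.random.default_rng(3)
    values = (rng.random((200, 12)) < 0.35).astype(float)
    return cs.GenotypeMatrix(values, coding=cs.DOMINANT)


def make_pair_fit(rng, n=2000, b_int=(0.3, -0.2), mains=((1.0, 0.2), (0.2, 1.0)),
                  noise_sd=1.0, freq=0.4):
    """Simulate one two-marker, two-response dataset and fit the pair model."""
    x1 = (rng.random(n) < freq).astype(float)
    x2 = (rng.random(n) < freq).astype(float)
    resp = []
    for j in range(2):
        resp.append(mains[j][0] * x1 + mains[j][1] * x2
                    + b_int[j] * x1 * x2 + noise_sd * rng.standard_normal(n))
    return cs.pairscan(x1, x2, np.column_stack(resp))
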