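import numpy as np
import pandas as pd
import pytest

import sparseclogit as scl


@pytest.fixture
def toy_pairs_df():
    """Two 1:1 strata, two covariates, well-formed."""
    return pd.DataFrame(
        {
            "stratum": ["a", "a", "b", "b"],
            "case": [1, 0, 0, 1],
            "x1": [1.0, 0.0, 0.0, 1.0],
            "x2": [0.0, 1.0, 1.0, 0.0],
        }
    )


@pytest.fixture
def small_matched():
    """Moderate 1:1 dataset with two real effects (N=300, p=5)."""
    sim = scl.simulate_matched(
        scl.SimulationDesign(
            n_strata=300,
            n_controls=1,
            n_predictors=5,
            beta_true=np.array([0.7, -0.7, 0.0, 0.0, 0.0]),
            exposure_prevalence=0.3,
            seed=42,
        )
    )
    return sim


@pytest.fixture
def small_1to3():
    """1:3 matched dataset (N=150, p=4)."""
    sim = scl.simulate_matched(
        scl.SimulationDesign(
            n_strata=150,
            n_controls=3,
            n_predictors=4,
            beta_true=np.array([0.6, -0.6, 0.0, 0.0]),
            exposure_prevalence=0.3,
            seed=7,
        )
    )
    return sim


def random_instance(rng, n_max=30, m_choices=(1, 2, 3, 4), p_max=5, prevalence=0.3):
    """One random small matched dataset with moderate true effects."""
    N = int(rng.integers(8, n_max + 1))
    M = int(rng.choice(m_choices))
    p = int(rng.integers(1, p_max + 1))
    beta_true = rng.normal(0.0, 0.5, p)
    sim = scl.simulate_matched(
        scl.SimulationDesign(
            n_strata=N, n_controls=M, n_predictors=p, beta_true=beta_true,
            exposure_prevalence=prevalence, seed=int(rng.integers(2**31 - 1)),
        )
    )
    return sim
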