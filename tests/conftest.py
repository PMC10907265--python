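import warnings

import numpy as np
import pandas as pd
import pytest

from fertgrowth import (
    ModelSpec,
    PredictorSpec,
    build_model_subset,
    fit,
    recovery_truth,
    simulate,
    standardize,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def toy_records():
    """Three women, two populations, one livestock predictor."""
    return pd.DataFrame(
        {
            "woman_id": ["w1", "w2", "w3"],
            "population_id": ["A", "A", "B"],
            "age": [20.0, 35.0, 61.0],
            "live_births": [1, 4, 7],
            "livestock": [0.0, 5.0, 50.0],
        }
    )


@pytest.fixture()
def toy_meta():
    return pd.DataFrame(
        {
            "population_id": ["A", "B"],
            "subsistence_type": ["hunter-gatherer", "agriculturalist"],
            "market_integration": ["low", "high"],
            "n_women": [2, 1],
        }
    )


@pytest.fixture(scope="session")
def small_fit():
    """One small but real posterior, shared across tests that only need
    *some* converged-ish draws (not a precise posterior)."""
    truth = recovery_truth(n_populations=4, women_per_population=150, seed=99)
    ds = simulate(truth)
    spec = PredictorSpec("focal", "zscore")
    dataset = build_model_subset(standardize(ds.records, spec), ds.meta, spec)
    mspec = ModelSpec(
        predictor=spec, woman_effect=False, chains=2, warmup=250, samples=250, seed=7
    )
    with warnings.catch_warnings():
        # short chains: convergence warnings are expected and irrelevant here
        warnings.simplefilter("ignore")
        post = fit(dataset, mspec)
    return truth, ds, post
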