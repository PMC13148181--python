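import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from svtvpfavar.factors import extract_factors_pca
from svtvpfavar.gibbs import ModelDims, SamplerConfig, run_gibbs
from svtvpfavar.preprocess import standardize
from svtvpfavar.simulate import ScenarioConfig, simulate_tvp_favar, small_tvp_var_preset


@pytest.fixture(scope="session")
def small_dataset():
    """A small three-variable TVP-VAR scenario with ground truth."""
    return simulate_tvp_favar(small_tvp_var_preset(T=80, seed=3))


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short Gibbs run on the small scenario, shared across tests."""
    dims = ModelDims(k=1, l=1, p=1, q=0, T=80)
    sampler = SamplerConfig(n_draws=400, n_burn=200, thin=1, seed=11)
    return run_gibbs(small_dataset.y, dims, sampler=sampler)


@pytest.fixture(scope="session")
def panel_dataset():
    """A medium factor-panel scenario for factor-block tests."""
    return simulate_tvp_favar(ScenarioConfig(T=60, n=40, k=2, l=1, p=2, q=1, seed=7))


@pytest.fixture(scope="session")
def standardized_panel(panel_dataset):
    X, _, _ = standardize(panel_dataset.panel.to_numpy())
    return np.asarray(X)
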