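import numpy as np
import pytest

import ratepath as rp
from ratepath.pipeline import rate_table_from_simulation


@pytest.fixture(scope="session")
def library():
    return rp.build_model_library()


@pytest.fixture(scope="session")
def b_dag4(library):
    return next(d for d in library if d.name == "B-DAG4")


@pytest.fixture(scope="session")
def a_dag4(library):
    return next(d for d in library if d.name == "A-DAG4")


def unit_residuals(dag):
    return {v: 1.0 for v in dag.nodes}


@pytest.fixture(scope="session")
def adjustment_sim():
    cfg = rp.CommunitySimConfig(seed=101, scenario="adjustment")
    return rp.simulate_transition_dataset(cfg)


@pytest.fixture(scope="session")
def adjustment_rates(adjustment_sim):
    return rate_table_from_simulation(adjustment_sim, single_resource="DOC")


@pytest.fixture(scope="session")
def replacement_sim():
    cfg = rp.CommunitySimConfig(seed=202, scenario="replacement", turnover_fraction=1.0)
    return rp.simulate_transition_dataset(cfg)


def population_correlation(dag, coefficients, residual_variances):
    """Exact correlation matrix implied by a generating parameter set."""
    sigma = rp.implied_covariance(dag, coefficients, residual_variances)
    d = np.sqrt(np.diag(sigma.to_numpy()))
    corr = sigma.to_numpy() / np.outer(d, d)
    import pandas as pd

    return pd.DataFrame(corr, index=sigma.index, columns=sigma.columns)
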