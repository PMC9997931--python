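import numpy as np
import pytest

from dispersim.preprocess import filter_low_expression, tmm_factors
from dispersim.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small preprocessed moderated-scenario dataset shared across tests."""
    cfg = SimConfig(
        n_genes=150,
        n_per_condition=25,
        scenario="moderated",
        fc_mean_max=1.3,
        seed=42,
    )
    dataset, truth = simulate_dataset(cfg)
    factors = tmm_factors(dataset)
    filtered, _ = filter_low_expression(dataset, factors)
    return {
        "config": cfg,
        "dataset": filtered,
        "truth": truth.subset(filtered.gene_ids),
        "factors": factors,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
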