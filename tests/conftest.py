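"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from loyburden.config import SimulationConfig, gigyf1_like_spec
from loyburden.synthetic import simulate_cohort, simulate_exome, simulate_loy_inputs


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_individuals=400, n_genes=30, mean_variants_per_gene=6, seed=101,
        carrier_gene_specs=(gigyf1_like_spec(),),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_sim(small_config, small_cohort):
    return simulate_exome(small_cohort, small_config)


@pytest.fixture(scope="session")
def small_sim_paths(small_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim_small")
    return small_sim.write(str(outdir))


@pytest.fixture(scope="session")
def small_measures(small_config, small_cohort) -> pd.DataFrame:
    return simulate_loy_inputs(small_cohort, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
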