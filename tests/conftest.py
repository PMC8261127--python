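import numpy as np
import pandas as pd
import pytest

from afcerna import SimulationConfig, generate_dataset
from afcerna.pipeline import RunConfig, run_all


def small_sim_config(**overrides) -> SimulationConfig:
    """A fast, reduced cohort with the same planted structure as the default."""
    base = dict(
        n_samples_per_group={"SR/SR": 10, "AF/SR": 12, "AF/AF": 14},
        n_genes=300,
        n_lncrna=30,
        n_modules=4,
        module_size=40,
        module_base_cor=0.75,
        trait_module_effects={1: ("susceptibility", 1.2), 3: ("persistence", 1.8)},
        n_mirnas=200,
        pairs_per_module=4,
        hub_partner_count=3,
        n_seed_genes=6,
        layer2_random_edges=100,
        layer2_planted_edges=40,
        hub_layer2_seed_edges=3,
        n_test_per_group={"SR/SR": 8, "AF/AF": 8},
        n_gene_sets=5,
        rng_seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_sim_config())


@pytest.fixture(scope="session")
def default_dataset():
    """The study-scale synthetic cohort (5,000 genes, 6 modules, 235 samples)."""
    return generate_dataset(SimulationConfig(rng_seed=1))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the study-scale cohort, shared across tests."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(out_dir=str(out), rng_seed=1)
    report = run_all(cfg)
    return cfg, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_expression(n_genes=20, n_samples=12, seed=0) -> pd.DataFrame:
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        r.normal(size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
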