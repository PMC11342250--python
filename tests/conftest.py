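import numpy as np
import pytest

import somagerm as sg


SMALL_TYPES = ("hub", "CySC", "GSC_spermatogonia", "early_cyst")


@pytest.fixture(scope="session")
def small_config() -> sg.SimConfig:
    return sg.SimConfig(
        n_genes=200,
        cell_types=SMALL_TYPES,
        cells_per_type_per_condition=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    adata, gt = sg.generate_counts(small_config)
    return adata, gt


@pytest.fixture(scope="session")
def small_norm(small_data):
    adata, _ = small_data
    return sg.normalize(adata)


@pytest.fixture(scope="session")
def small_db(small_config) -> sg.LRDatabase:
    return sg.synthetic_lrdb(small_config, n_decoy_pairs=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
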