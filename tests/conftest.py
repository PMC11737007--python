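from importlib import resources

import pandas as pd
import pytest

import dietpaf as dp


@pytest.fixture(scope="session")
def config():
    """The bundled Italian 2020 analysis configuration."""
    return dp.load_config(dp.bundled_config_path())


@pytest.fixture(scope="session")
def published_paf():
    """Published PAF table (percent, with 95% CI bounds) per pair and sex."""
    path = resources.files("dietpaf").joinpath("data/published_paf.csv")
    return pd.read_csv(str(path))


@pytest.fixture()
def processed_meat_men(config):
    return config.summaries[("processed_meat", "male")]
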