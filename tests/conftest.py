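import numpy as np
import pandas as pd
import pytest

from fallmr import phenotyping, synthdata


@pytest.fixture(scope="session")
def small_config():
    return synthdata.SimConfig(
        n_individuals=1500, n_variants=60, ld_block_size=10,
        within_block_r=0.6, seed=7, true_causal_effect=0.2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthdata.simulate_traits(synthdata.simulate_genotypes(small_config), small_config)


@pytest.fixture(scope="session")
def code_list():
    return phenotyping.default_code_list()


@pytest.fixture(scope="session")
def event_log(small_cohort, code_list):
    events, no_records = synthdata.simulate_event_log(small_cohort, code_list, seed=11)
    return events, no_records


def make_instruments(beta_x, se_x, beta_y, se_y):
    """Assemble an instrument table from parallel arrays."""
    return pd.DataFrame(
        {
            "beta_x": np.asarray(beta_x, float),
            "se_x": np.asarray(se_x, float),
            "beta_y": np.asarray(beta_y, float),
            "se_y": np.asarray(se_y, float),
        }
    )
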