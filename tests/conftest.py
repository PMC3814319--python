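import numpy as np
import pytest

from kirco.ligands import load_default_epitope_config, load_default_interaction_table
from kirco.simulate import default_sim_config, simulate_cohort


@pytest.fixture(scope="session")
def epitope_config():
    return load_default_epitope_config()


@pytest.fixture(scope="session")
def interaction_table():
    return load_default_interaction_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A small study-shaped cohort (12 pairs + 5 unrelated), with truth."""
    cfg = default_sim_config(1234, n_pairs=12, n_unrelated=5)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20131031)
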