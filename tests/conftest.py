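import pytest

from prediasim import load_parameters
from prediasim.synthetic_data import default_life_table


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def small_run(params, life_table):
    """A modest paired run (all arms, age 40, n=4000) reused across tests."""
    from prediasim.model import run_age
    return run_age(params, 40, seed=20240, life_table=life_table, n=4000)
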