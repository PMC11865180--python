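import pytest

from ensembleyn.presets import EXP1_AVERAGING, EXP2_SIMILARITY
from ensembleyn.synthetic_data import simulate_experiment


@pytest.fixture(scope="session")
def exp1_avg_table():
    """Six averaging observers on the orientation design."""
    return simulate_experiment(1, EXP1_AVERAGING, 6, seed=101)


@pytest.fixture(scope="session")
def exp2_sim_table():
    """Six similarity observers on the color design."""
    return simulate_experiment(2, EXP2_SIMILARITY, 6, seed=202)


@pytest.fixture(scope="session")
def exp4_table():
    """Five averaging observers on the two-dimension orientation design."""
    return simulate_experiment(4, EXP1_AVERAGING, 5, seed=303)
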