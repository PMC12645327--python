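import numpy as np
import pytest

from traitphylo.priors import BirthDeathParams
from traitphylo.simulate import SimulationConfig, simulate_time_tree
from traitphylo.substitution import ClockModel, CovarionModel
from traitphylo.traits import TraitMatrix
from traitphylo.trees import parse_tree


@pytest.fixture
def three_tip_tree():
    return parse_tree("(A:2,(B:1,C:1):1);")


@pytest.fixture
def six_tip_tree():
    return parse_tree("((A:1.0,(B:0.5,(C:0.3,D:0.3):0.2):0.5):0.4,(E:0.9,F:0.9):0.5);")


@pytest.fixture
def default_model():
    return CovarionModel(pi_present=0.35, alpha=0.5, switch_rate=0.6, overall_rate=0.9)


@pytest.fixture
def strict_clock():
    return ClockModel(kind="strict", mean_rate=0.7)


@pytest.fixture
def three_taxon_matrix():
    return TraitMatrix(
        taxa=["A", "B", "C"],
        states=np.array([[1, 0, 1, -1], [0, 0, 1, 1], [1, 1, 0, 1]], dtype=np.int8),
        char_ids=["c1", "c2", "c3", "c4"],
    )


def random_time_tree(seed: int, n_tips: int = 6):
    """Small random birth-death tree for property tests."""
    cfg = SimulationConfig(
        n_extant=n_tips,
        bd=BirthDeathParams(lam=1.0, mu=0.2, rho=1.0),
        origin_age=2.5,
        seed=seed,
        n_characters_per_level={1: 1},
    )
    return simulate_time_tree(cfg)
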