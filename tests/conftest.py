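import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from l1dynamics import (
    BisseParams,
    SimConfig,
    TipStates,
    TreeSample,
    simulate_bisse,
)

#: Best-fit rates of the published model comparison (mu0 = mu1 = 0 row),
#: used throughout as the realistic simulation truth.
PAPER_PARAMS = BisseParams(10.0, 412.0, 0.0, 0.0, 31.0, 360.0)


@pytest.fixture(scope="session")
def paper_params() -> BisseParams:
    return PAPER_PARAMS


@pytest.fixture(scope="session")
def small_sim():
    """A 10-tip dataset simulated at the published best-fit rates."""
    return simulate_bisse(SimConfig(params=PAPER_PARAMS, n_tips=10, seed=3))


@pytest.fixture(scope="session")
def medium_sim():
    """A 60-tip dataset at the published best-fit rates."""
    return simulate_bisse(SimConfig(params=PAPER_PARAMS, n_tips=60, seed=17))


@pytest.fixture(scope="session")
def large_sim():
    """A 150-tip dataset at the published best-fit rates."""
    return simulate_bisse(SimConfig(params=PAPER_PARAMS, n_tips=150, seed=11))


@pytest.fixture(scope="session")
def yule_tree():
    """A 20-tip pure-birth tree with every tip in the low-activity state."""
    sim = simulate_bisse(
        SimConfig(params=BisseParams(3, 3, 0, 0, 0, 0), n_tips=20, seed=7, root_state=0)
    )
    states = TipStates({lab: 0 for lab in sim.tree.tip_labels})
    return sim.tree, states
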