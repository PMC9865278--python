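import numpy as np
import pandas as pd
import pytest

from eoscreen import composition as comp
from eoscreen import synthetic as syn


@pytest.fixture(scope="session")
def rosemary():
    """The packaged six-cultivar composition panel (means ± SDs)."""
    return comp.rosemary_panel()


@pytest.fixture(scope="session")
def rosemary_replicates(rosemary):
    """Three seeded synthetic replicates per cultivar drawn from the panel."""
    return syn.gen_composition_replicates(rosemary, n_rep=3, seed=0)


@pytest.fixture()
def simple_ladder():
    return comp.AlkaneLadder({10: 10.00, 11: 12.00})


@pytest.fixture()
def toy_matrix():
    """Small all-benefit decision matrix with a clear best alternative."""
    return pd.DataFrame(
        {
            "c1": [3.0, 4.0, 5.0],
            "c2": [1.0, 2.0, 4.0],
            "c3": [2.0, 2.0, 6.0],
        },
        index=["a", "b", "best"],
    )
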