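import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rrvote as rv

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_voter_matrix():
    """Two voters, three items on a 0-5 scale; produces an exact tie in round 2."""
    frame = pd.DataFrame(
        {"P": [5.0, 0.0], "Q": [4.0, 4.0], "R": [0.0, 5.0]}, index=["v1", "v2"]
    )
    return rv.ScoreMatrix(frame, scale_max=5.0)


@pytest.fixture
def bloc_60_40():
    return rv.disjoint_bloc_panel(60, 40)


@pytest.fixture
def bloc_80_20():
    return rv.disjoint_bloc_panel(80, 20)


def random_panel(rng, max_side=8, scale_max=5.0, abstain_prob=0.15, integer=True):
    """A small random score matrix with abstentions, for oracle comparisons."""
    n_p = int(rng.integers(1, max_side + 1))
    n_i = int(rng.integers(1, max_side + 1))
    if integer:
        vals = rng.integers(0, int(scale_max) + 1, size=(n_p, n_i)).astype(float)
    else:
        vals = rng.uniform(0, scale_max, size=(n_p, n_i))
    mask = rng.random((n_p, n_i)) < abstain_prob
    vals[mask] = np.nan
    frame = pd.DataFrame(
        vals,
        index=[f"p{i}" for i in range(n_p)],
        columns=[f"q{j}" for j in range(n_i)],
    )
    return rv.ScoreMatrix(frame, scale_max=scale_max)
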