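import numpy as np
import pytest

from normknock import SimConfig, Trajectory
from normknock.norms import N_NORMS, norm_from_string


@pytest.fixture
def rs():
    """Factory for seeded legacy RandomState generators."""
    return lambda seed=0: np.random.RandomState(seed)


@pytest.fixture
def tiny_config():
    return SimConfig(n_agents=6, generations=3, rounds=5, benefit=5.0, cost=1.0)


def make_trajectory(majorities, coop, n_agents=10, config=None, seed=0):
    """Synthetic trajectory whose per-generation majority is prescribed.

    ``majorities`` is a list of norm labels; the named norm gets most of
    the population each generation, the remainder goes to ALLB (or ALLG
    when ALLB itself is the majority).
    """
    g = len(majorities)
    assert len(coop) == g
    counts = np.zeros((g, N_NORMS), dtype=np.int64)
    for t, label in enumerate(majorities):
        code = norm_from_string(label)
        filler = 15 if code == 0 else 0
        counts[t, code] = n_agents - 1
        counts[t, filler] = 1
    if config is None:
        config = SimConfig(n_agents=n_agents, generations=g, rounds=10)
    return Trajectory(np.asarray(coop, dtype=float), counts, config, seed)
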