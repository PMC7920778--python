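import numpy as np
import pytest

from cspcoex import CommunityParams, CommunityState, MatingProbabilities


@pytest.fixture
def caption_probs() -> MatingProbabilities:
    """The worked-example acceptance probabilities (Y is the stronger interferer)."""
    return MatingProbabilities(
        pXX=0.4, qXX=0.4, pXY=0.8, pYY=0.8, pYX=0.4, qYY=0.8
    )


@pytest.fixture
def low_overlap(caption_probs) -> CommunityParams:
    """Coexistence regime: c = 0.4 with defaults r=25, v=1, b=0.3."""
    return CommunityParams(c=0.4, probs=caption_probs)


@pytest.fixture
def high_overlap(caption_probs) -> CommunityParams:
    """Exclusion regime: c = 0.9 with defaults r=25, v=1, b=0.3."""
    return CommunityParams(c=0.9, probs=caption_probs)


@pytest.fixture
def even_state() -> CommunityState:
    return CommunityState(1.0, 1.0)


def random_probs(rng: np.random.Generator, low: float = 0.05) -> MatingProbabilities:
    v = rng.uniform(low, 1.0, 8)
    return MatingProbabilities(
        pXX=v[0], pXY=v[1], pYX=v[2], pYY=v[3],
        qXX=v[4], qYY=v[5], qXY=v[6], qYX=v[7],
    )
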