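import numpy as np
import pytest
from hypothesis import settings

from irredclass import BackgroundModel, Sequence

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_pair():
    """The alternating binary pair with two irredundant patterns."""
    return Sequence("s1", "abababab"), Sequence("s2", "babababa")


@pytest.fixture
def counter_pair():
    """The pair used for the exposed-occurrence counter walkthrough."""
    return Sequence("s1", "aabababab"), Sequence("s2", "babacacac")


@pytest.fixture
def calcium_loop():
    """A 26-residue segment carrying the d.dg.g.i...e pattern twice."""
    return Sequence("loop", "dadgggdistketvdedgsgtidfee")


@pytest.fixture
def binary_bg():
    return BackgroundModel.uniform("ab")


def random_sequence(rng: np.random.Generator, length: int, alphabet: str) -> Sequence:
    return Sequence(
        f"r{rng.integers(10**6)}", "".join(rng.choice(list(alphabet), size=length))
    )
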