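import numpy as np
import pytest

from ddiblocks import InteractionNetwork, TypeAlphabet


@pytest.fixture
def k3_alphabet():
    return TypeAlphabet(("synergistic", "additive", "antagonistic"), ordered=True)


@pytest.fixture
def toy_net(k3_alphabet):
    """Six drugs in two clean blocks; three pairs deliberately unobserved."""
    obs = {
        ("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 1,
        ("D", "E"): 1, ("D", "F"): 1, ("E", "F"): 1,
        ("A", "D"): 0, ("A", "E"): 0, ("B", "D"): 0,
        ("B", "F"): 0, ("C", "E"): 0, ("C", "F"): 2,
    }
    return InteractionNetwork("ABCDEF", k3_alphabet, obs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_network(rng, n_drugs=8, k=3, density=0.6, ordered=True):
    alphabet = TypeAlphabet(tuple(f"t{i}" for i in range(k)), ordered=ordered)
    drugs = [f"D{i}" for i in range(n_drugs)]
    obs = {}
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            if rng.random() < density:
                obs[(drugs[i], drugs[j])] = int(rng.integers(k))
    return InteractionNetwork(drugs, alphabet, obs)
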