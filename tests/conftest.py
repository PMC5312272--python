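import numpy as np
import pytest
from hypothesis import settings

from sigrev.ranking import RankedList

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_ranked_list(rng, n, node_id="r"):
    feats = [f"g{i:04d}" for i in range(n)]
    perm = rng.permutation(n)
    return RankedList(node_id=node_id, features=tuple(feats[i] for i in perm))


@pytest.fixture
def small_list():
    return RankedList(node_id="toy", features=("a", "b", "c", "d", "e", "f"))
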