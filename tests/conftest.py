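import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy():
    from modesign.synthetic import make_toy_problem

    return make_toy_problem(L=6, A=4, conflict_fraction=0.5, seed=7)


@pytest.fixture
def small_problem():
    from modesign.problem import make_problem

    return make_problem("ACDEFG", [2, 4], alphabet=None, state_names=["a", "b"])


def brute_force_fronts(obj: np.ndarray) -> list[list[int]]:
    """O(n^2 m) oracle: count dominators per point and peel fronts."""
    n = obj.shape[0]
    remaining = set(range(n))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = False
            for j in remaining:
                if j != i and np.all(obj[j] <= obj[i]) and np.any(obj[j] < obj[i]):
                    dominated = True
                    break
            if not dominated:
                front.append(i)
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts
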