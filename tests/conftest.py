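import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from siig import DirectionSpec, TraitMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def naive_siig(values, benefit_flags):
    """Independent pure-Python reference for the whole scoring chain.

    Plain loops, no numpy: column root-sum-of-squares normalization,
    directed extrema, Euclidean distances, closeness score.
    """
    n = len(values)
    m = len(values[0])
    norms = [math.sqrt(sum(values[i][j] ** 2 for i in range(n))) for j in range(m)]
    r = [[values[i][j] / norms[j] for j in range(m)] for i in range(n)]
    r_plus, r_minus = [], []
    for j in range(m):
        col = [r[i][j] for i in range(n)]
        if benefit_flags[j]:
            r_plus.append(max(col))
            r_minus.append(min(col))
        else:
            r_plus.append(min(col))
            r_minus.append(max(col))
    scores = []
    for i in range(n):
        dp = math.sqrt(sum((r[i][j] - r_plus[j]) ** 2 for j in range(m)))
        dm = math.sqrt(sum((r[i][j] - r_minus[j]) ** 2 for j in range(m)))
        scores.append(0.5 if dp + dm == 0 else dm / (dp + dm))
    return scores


@pytest.fixture
def two_trait_matrix():
    return TraitMatrix.from_arrays(
        ["a", "b", "c"], ["t1", "t2"], [[3.0, 10.0], [4.0, 20.0], [0.1, 30.0]]
    )


@pytest.fixture
def mixed_directions():
    return DirectionSpec({"t1": "benefit", "t2": "cost"})


def random_positive_matrix(rng, n, m):
    ids = [f"g{i}" for i in range(n)]
    traits = [f"t{j}" for j in range(m)]
    return TraitMatrix.from_arrays(ids, traits, rng.uniform(0.5, 10.0, size=(n, m)))
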