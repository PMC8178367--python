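import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pathperturb.models import ExpressionMatrix, PathwayGraph, RunConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def config():
    return RunConfig(permutations=99, rng_seed=7)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, handcrafted values (log2 scale)."""
    values = pd.DataFrame(
        [
            [10.0, 10.2, 8.0, 8.1],   # clear up
            [6.0, 6.1, 8.0, 8.2],     # clear down
            [7.0, 7.1, 7.05, 7.02],   # unchanged
        ],
        index=["gA", "gB", "gC"],
        columns=["t1", "t2", "c1", "c2"],
    )
    cond = {"t1": "treated", "t2": "treated", "c1": "control", "c2": "control"}
    return ExpressionMatrix(values, cond)


@pytest.fixture
def chain_pathway():
    """a - b - c chain."""
    return PathwayGraph(
        "chain", "chain pathway", frozenset(["a", "b", "c"]),
        (("a", "b", 1), ("b", "c", 1)),
    )
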