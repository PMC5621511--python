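import numpy as np
import pytest

import macrorich as mr


@pytest.fixture(scope="session")
def world():
    """A small source–sink world shared across read-only tests."""
    env = mr.make_environment((15, 15), seed=101)
    ranges = mr.make_ranges(30, env, seed=102)
    grid = mr.stack_richness(ranges)
    matrix = mr.build_matrix(ranges)
    return {"env": env, "ranges": ranges, "grid": grid, "matrix": matrix}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_binary_matrix(rng, shape, fill=0.35, min_line=1):
    """Random 0/1 matrix with no all-zero rows or columns."""
    while True:
        M = (rng.random(shape) < fill).astype(int)
        if (M.sum(axis=1) >= min_line).all() and (M.sum(axis=0) >= min_line).all():
            return M
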