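import numpy as np
import pytest

from mirmotif import ExpressionProfile, ProfileSet, TimeGrid


@pytest.fixture
def grid19() -> TimeGrid:
    return TimeGrid.uniform(0.0, 6.0, 19)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240218)


def make_profile(values, sid="x", role="miRNA", grid=None):
    values = np.asarray(values, dtype=float)
    grid = grid or TimeGrid(tuple(range(len(values))))
    return ExpressionProfile(sid, role, values, grid)


def random_profile_set(rng, n, q, role="miRNA"):
    grid = TimeGrid(tuple(range(q)))
    return ProfileSet(
        grid,
        (
            ExpressionProfile(f"s{i}", role, rng.normal(size=q), grid)
            for i in range(n)
        ),
    )
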