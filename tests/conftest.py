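import numpy as np
import pytest

from hequity import Distribution, Unit


@pytest.fixture
def equal_dist():
    """10 units, equal population and equal resource: every index is 0."""
    return Distribution(
        [Unit(f"u{i}", 100.0, 20.0, ses=float(i), group=f"g{i % 2}") for i in range(10)]
    )


@pytest.fixture
def two_unit_dist():
    """2 equal-population units with resource shares (0.2, 0.8)."""
    return Distribution([Unit("a", 50.0, 20.0), Unit("b", 50.0, 80.0)])


def make_random_dist(rng, n=None, with_groups=False, with_ses=False, n_groups=3):
    """Random positive-resource distribution for property tests."""
    n = n or int(rng.integers(2, 12))
    pops = rng.uniform(10, 1000, size=n)
    res = rng.uniform(0.1, 100, size=n)
    units = [
        Unit(
            f"u{i}",
            float(pops[i]),
            float(res[i]),
            ses=float(rng.uniform()) if with_ses else None,
            group=f"g{int(rng.integers(n_groups))}" if with_groups else None,
        )
        for i in range(n)
    ]
    return Distribution(units)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
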