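import numpy as np
import pytest

from hic4d import (
    ContactMap,
    assemble_series,
    build_restraints,
    make_toy_trajectory,
    simulate_hic,
)


@pytest.fixture(scope="session")
def unravel_series():
    return simulate_hic(make_toy_trajectory("unravel"))


@pytest.fixture(scope="session")
def swing_series():
    return simulate_hic(make_toy_trajectory("swing"))


@pytest.fixture(scope="session")
def unravel_restraints(unravel_series):
    return build_restraints(unravel_series)


@pytest.fixture
def random_map():
    """A random symmetric 11x11 map with a fixed seed."""
    rng = np.random.default_rng(7)
    a = rng.random((11, 11)) * 10
    m = (a + a.T) / 2
    np.fill_diagonal(m, 0.0)
    return ContactMap(matrix=m, bin_size=50_000, time=0.0, chrom="toy")


def two_block_map(block: int = 6, high: float = 10.0, low: float = 1.0):
    """Checkerboard map: two blocks with strong within- and weak
    between-block contacts, plus a distance-decay background."""
    n = 2 * block
    labels = np.array([0] * block + [1] * block)
    m = np.where(labels[:, None] == labels[None, :], high, low).astype(float)
    idx = np.arange(n)
    decay = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
    m = m * decay
    np.fill_diagonal(m, 0.0)
    return ContactMap(matrix=m, bin_size=50_000, time=0.0, chrom="toy")


@pytest.fixture
def static_series():
    """Six identical maps from a single frozen conformation (a static
    chromosome observed at six times)."""
    traj = make_toy_trajectory("unravel")
    frozen = traj.coords[2]
    d = np.linalg.norm(frozen[:, None] - frozen[None, :], axis=-1)
    np.fill_diagonal(d, 1.0)
    m = d ** (-1 / 0.6)
    np.fill_diagonal(m, 0.0)
    maps = [
        ContactMap(matrix=m.copy(), bin_size=50_000, time=float(t), chrom="toy")
        for t in range(6)
    ]
    return assemble_series(maps)
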