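import numpy as np
import pytest

from penphi import (
    get_model,
    power_divergence,
)


@pytest.fixture(scope="session")
def hw():
    return get_model("example3-hw")


@pytest.fixture(scope="session")
def ex1():
    return get_model("example1")


@pytest.fixture(scope="session")
def ex2():
    return get_model("example2")


@pytest.fixture(scope="session")
def pd():
    """Power-divergence generator factory (cached per index)."""
    cache = {}

    def make(lam):
        if lam not in cache:
            cache[lam] = power_divergence(lam)
        return cache[lam]

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(20180329)


def brute_force_theta(q, model, phi, h, coarse=2001, fine_step=1e-6):
    """Independent grid-search oracle for the 1-d minimum penalized
    divergence fit: coarse scan of the clamped box, then an exhaustive
    1e-6-step scan of the bracketing window.  Uses only the divergence
    evaluator, never the package optimizer."""
    from penphi.divergences import penalized_divergence_batch

    lo, hi = model.clamped_bounds()
    lo, hi = float(lo[0]), float(hi[0])

    def scan(grid):
        P = model.probs_batch(grid)
        Q = np.broadcast_to(q, P.shape)
        vals = penalized_divergence_batch(Q, P, phi, h)
        return grid[int(np.argmin(vals))]

    g = np.linspace(lo, hi, coarse)
    t0 = scan(g)
    step = (hi - lo) / (coarse - 1)
    a, b = max(lo, t0 - 2 * step), min(hi, t0 + 2 * step)
    return scan(np.arange(a, b, fine_step))
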