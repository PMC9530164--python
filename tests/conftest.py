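import numpy as np
import pytest

from evospectra.web import FoodWeb


@pytest.fixture
def single_producer():
    """One producer, k=1, alpha=0.2; closed-form equilibrium S* = 0.8."""
    return FoodWeb(
        ids=[0], alpha=[0.2], is_producer=[True],
        eta=np.zeros((1, 1)), biomass=[0.8], beta=1.0, k=1.0,
    )


@pytest.fixture
def pair_web():
    """Producer (alpha=0.1) + consumer (alpha=0.2), beta=1, eta=0.5.

    Hand-solved equilibrium S* = (0.4, 1.0); community matrix
    [[-0.4, -0.2], [0.5, 0]]; eigenvalues -0.2 +/- 0.2449i.
    """
    eta = np.zeros((2, 2))
    eta[1, 0] = 0.5
    return FoodWeb(
        ids=[0, 1], alpha=[0.1, 0.2], is_producer=[True, False],
        eta=eta, biomass=[0.4, 1.0], beta=1.0, k=1.0,
    )


def random_feasible_web(rng, max_n=8, beta=None):
    """Assemble a random feasible web by greedy attachment, for oracles.

    Species are added one at a time (producers or single/double-resource
    consumers with Table-1 parameter draws); a candidate is kept only if
    the analytic steady state stays feasible.  Independent of the
    simulator's relaxation machinery.
    """
    from evospectra.web import steady_state

    if beta is None:
        beta = rng.choice([0.25, 0.5, 0.75, 0.9, 1.0])
    web = FoodWeb(
        ids=[0], alpha=[rng.uniform(0.05, 0.5)], is_producer=[True],
        eta=np.zeros((1, 1)), biomass=[0.0], beta=beta, k=1.0,
    )
    next_id = 1
    target = rng.integers(2, max_n + 1)
    for _ in range(60):
        if web.n >= target:
            break
        n = web.n
        is_prod = rng.random() < 0.5
        eta = np.zeros((n + 1, n + 1))
        eta[:n, :n] = web.eta
        if not is_prod:
            picks = rng.permutation(n)[: (2 if (n >= 2 and rng.random() < 0.5) else 1)]
            for p in picks:
                eta[n, p] = rng.uniform(0.01, 1.0)
        cand = FoodWeb(
            np.append(web.ids, next_id),
            np.append(web.alpha, rng.uniform(0.05, 0.5)),
            np.append(web.is_producer, is_prod),
            eta,
            np.append(web.biomass, 0.0),
            beta, 1.0,
        )
        ss = steady_state(cand)
        if ss.unique and ss.feasible:
            cand.biomass = ss.populations.copy()
            web = cand
            next_id += 1
    ss = steady_state(web)
    web.biomass = ss.populations.copy()
    return web
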