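import numpy as np
import pytest

from coalsim import Coalition, GameConfig, Offer, make_agent


@pytest.fixture
def game543():
    """The common 5(4-3-2) game, payoff 100, grand coalition prohibited."""
    return GameConfig(resources=(4, 3, 2), decision_point=5, payoff=100)


@pytest.fixture
def game543_grand():
    return GameConfig(
        resources=(4, 3, 2), decision_point=5, payoff=100,
        allow_grand_coalition=True,
    )


@pytest.fixture
def game111():
    """The simplest 2(1-1-1) game."""
    return GameConfig(resources=(1, 1, 1), decision_point=2, payoff=100)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def seated_agents(strategy, seed=0, n=3, **params):
    """Three agents of one strategy, seated at A, B, C."""
    agents = []
    for position in range(n):
        agent = make_agent(
            strategy, np.random.default_rng([seed, position]), **params
        )
        agent.position = position
        agents.append(agent)
    return agents


@pytest.fixture
def equity_triad():
    return seated_agents("equity")


def worked_example_offers():
    """The three Phase-I offers of the engine's worked example:
    A: AC with A=60/C=40; B: BC with B=55/C=45; C: BC split 50/50."""
    return [
        Offer.make(0, Coalition.of(0, 2), {0: 60, 2: 40}),
        Offer.make(1, Coalition.of(1, 2), {1: 55, 2: 45}),
        Offer.make(2, Coalition.of(1, 2), {1: 50, 2: 50}),
    ]
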