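import numpy as np
import pytest

from coalsim import (
    Coalition,
    Offer,
    RatifyChoice,
    Selection,
    Status,
    build_board,
    ratify,
    resolve_round,
    run_alt_offers_game,
    solicit_alternative,
    to_tentative,
)
from coalsim.agents import PASS, CounterProposal, EquityAgent
from coalsim.altoffers import (
    BACK_TO_PHASE_I,
    FORMED,
    NEW_TENTATIVE,
    AlternativeOffer,
    TentativeCoalition,
    excluded_position,
)
from coalsim.onestep import ProtocolError

from conftest import seated_agents, worked_example_offers


def tentative_bc_55_45():
    return TentativeCoalition(
        coalition=Coalition.of(1, 2), shares=((1, 55), (2, 45)), origin="phase3"
    )


class TestToTentative:
    def test_unanimous_entry_becomes_tentative(self, game543):
        board = build_board(worked_example_offers())
        b_entry = [e for e in board if e.proposers == (1,)][0]
        a_entry = [e for e in board if e.proposers == (0,)][0]
        selections = [
            Selection(0, a_entry),
            Selection(1, b_entry),
            Selection(2, b_entry),
        ]
        result = resolve_round(board, selections, game543)
        tentative = to_tentative(result)
        assert tentative is not None
        assert tentative.coalition.label == "BC"
        assert tentative.allocation == {1: 55, 2: 45}

    def test_no_unanimity_gives_none(self, game543):
        board = build_board(worked_example_offers())
        selections = [
            Selection(s, [e for e in board if s in e.coalition][0])
            for s in range(3)
        ]
        # A -> AC, B -> first BC entry, C -> same-coalition entries differ
        result = resolve_round(board, selections, game543)
        if result.formed is None:
            assert to_tentative(result) is None

    def test_unanimous_grand_coalition(self, game543_grand):
        offers = [
            Offer.make(p, Coalition.of(0, 1, 2), {0: 40, 1: 30, 2: 30})
            for p in range(3)
        ]
        board = build_board(offers)
        entry = board.entries[0]
        result = resolve_round(
            board, [Selection(p, entry) for p in range(3)], game543_grand
        )
        tentative = to_tentative(result)
        assert tentative.coalition.label == "ABC"
        assert excluded_position(game543_grand, tentative) is None


class TestSolicitAlternative:
    def test_equity_excluded_makes_valid_dyadic_offer(self, game543, rng):
        agent = seated_agents("equity")[0]  # position A, excluded from BC
        alternative = solicit_alternative(
            tentative_bc_55_45(), agent, game543, rng
        )
        assert isinstance(alternative, AlternativeOffer)
        assert alternative.proposer == 0
        assert alternative.target in (1, 2)
        assert alternative.offer.coalition.members == {0, alternative.target}

    def test_soliciting_a_member_is_an_error(self, game543, rng):
        agent = seated_agents("equity")[1]  # B is inside the tentative BC
        with pytest.raises(ProtocolError):
            solicit_alternative(tentative_bc_55_45(), agent, game543, rng)

    def test_pass_is_allowed(self, game543, rng):
        agent = seated_agents("equity")[0]
        agent.counter = lambda view: PASS
        assert solicit_alternative(tentative_bc_55_45(), agent, game543, rng) is PASS

    def test_non_dyadic_counter_is_rejected(self, game543, rng):
        agent = seated_agents("equity")[0]
        bad = CounterProposal(
            target=2,
            offer=Offer.make(0, Coalition.of(0, 1), {0: 60, 1: 40}),  # not {A,C}
        )
        agent.counter = lambda view: bad
        with pytest.raises(ProtocolError):
            solicit_alternative(tentative_bc_55_45(), agent, game543, rng)


def alternative_ac(c_share=50):
    return AlternativeOffer(
        proposer=0,
        target=2,
        offer=Offer.make(0, Coalition.of(0, 2), {0: 100 - c_share, 2: c_share}),
    )


class TestRatify:
    def test_all_ratify_forms_tentative(self, game543):
        result = ratify(
            tentative_bc_55_45(),
            alternative_ac(),
            {1: RatifyChoice.RATIFY, 2: RatifyChoice.RATIFY},
            game543,
        )
        assert result.kind == FORMED
        assert result.tentative.allocation == {1: 55, 2: 45}

    def test_target_defection_creates_new_tentative(self, game543):
        result = ratify(
            tentative_bc_55_45(),
            alternative_ac(c_share=50),
            {1: RatifyChoice.RATIFY, 2: RatifyChoice.ALTERNATIVE},
            game543,
        )
        assert result.kind == NEW_TENTATIVE
        assert result.tentative.coalition.label == "AC"
        assert result.tentative.allocation == {0: 50, 2: 50}
        # the excluded bargainer's identity strictly changes: B is now out
        assert excluded_position(game543, result.tentative) == 1

    def test_none_goes_back_to_phase_one(self, game543):
        from dataclasses import replace

        cfg = replace(game543, allow_no_selection=True)
        result = ratify(
            tentative_bc_55_45(),
            alternative_ac(),
            {1: RatifyChoice.RATIFY, 2: RatifyChoice.NONE},
            cfg,
        )
        assert result.kind == BACK_TO_PHASE_I

    def test_none_while_disabled_is_an_error(self, game543):
        with pytest.raises(ProtocolError):
            ratify(
                tentative_bc_55_45(),
                None,
                {1: RatifyChoice.RATIFY, 2: RatifyChoice.NONE},
                game543,
            )

    def test_non_target_cannot_choose_alternative(self, game543):
        with pytest.raises(ProtocolError):
            ratify(
                tentative_bc_55_45(),
                alternative_ac(),
                {1: RatifyChoice.ALTERNATIVE, 2: RatifyChoice.RATIFY},
                game543,
            )


class OverbiddingAgent(EquityAgent):
    """Equity bargainer that, when excluded, overbids with an equal split."""

    def counter(self, view):
        target = 2 if 2 in view.tentative.coalition else 1
        dyad = Coalition.of(self.position, target)
        half = view.config.payoff // 2
        return CounterProposal(
            target,
            Offer.make(self.position, dyad, {self.position: half, target: half}),
        )


class ImprovingAgent(EquityAgent):
    """Counters with target's current share + 1 granule whenever affordable."""

    def counter(self, view):
        config = view.config
        from coalsim import feasible_coalitions

        feas = feasible_coalitions(config)
        for target in sorted(view.tentative.coalition):
            dyad = Coalition.of(self.position, target)
            if dyad not in feas:
                continue
            bid = view.tentative.allocation[target] + config.payoff_granularity
            if bid <= config.payoff:
                return CounterProposal(
                    target,
                    Offer.make(
                        self.position, dyad,
                        {self.position: config.payoff - bid, target: bid},
                    ),
                )
        return PASS


def seated(cls, positions=(0, 1, 2)):
    agents = []
    for position in positions:
        agent = cls(np.random.default_rng([17, position]))
        agent.position = position
        agents.append(agent)
    return agents


class TestRunAltOffersGame:
    def test_equity_triad_ratifies_bc_60_40(self, game543, equity_triad, rng):
        # A's best counter gives C at most ~1/3 of the payoff, below C's 40
        outcome = run_alt_offers_game(game543, equity_triad, rng)
        assert outcome.status is Status.FORMED
        assert outcome.coalition.label == "BC"
        assert outcome.allocation == {1: 60, 2: 40}
        assert outcome.rounds_used == 1
        actions = [e.action for e in outcome.events]
        assert "tentative" in actions and "ratify" in actions
        assert "defect" not in actions

    def test_overbidding_excluded_agent_triggers_defection(self, game543, rng):
        agents = seated(OverbiddingAgent)
        outcome = run_alt_offers_game(game543, agents, rng)
        actions = [e.action for e in outcome.events]
        assert "defect" in actions  # 50 > C's tentative 40 tempts C away

    def test_max_rounds_reached_mid_loop(self, game543, rng):
        from dataclasses import replace
        from test_onestep import stubborn_triad

        cfg = replace(game543, max_rounds=2)
        outcome = run_alt_offers_game(cfg, stubborn_triad(), rng)
        assert outcome.status is Status.NO_AGREEMENT
        assert outcome.rounds_used == 2

    def test_grand_tentative_skips_alternative_phase(self, game543_grand, rng):
        class GrandAgent(EquityAgent):
            def propose(self, view):
                return Offer.make(
                    self.position,
                    Coalition.of(0, 1, 2),
                    {0: 40, 1: 30, 2: 30},
                )

            def select(self, view):
                return view.eligible[0]

        outcome = run_alt_offers_game(game543_grand, seated(GrandAgent), rng)
        assert outcome.status is Status.FORMED
        assert outcome.coalition.label == "ABC"
        phases = {e.phase for e in outcome.events}
        assert "IV" not in phases  # nobody is excluded, so no counteroffer

    def test_strictly_improving_defections_terminate(self, game543, rng):
        outcome = run_alt_offers_game(game543, seated(ImprovingAgent), rng)
        assert outcome.status in (Status.FORMED, Status.NO_AGREEMENT)
        assert outcome.rounds_used <= game543.max_rounds
        cap = game543.payoff // game543.payoff_granularity
        for rnd in range(1, outcome.rounds_used + 1):
            defects = [
                e for e in outcome.events
                if e.action == "defect" and e.round == rnd
            ]
            assert len(defects) <= cap + 1  # per-round defection cap holds
        if outcome.status is Status.FORMED:
            assert sum(outcome.allocation.values()) == game543.payoff

    def test_no_outcome_without_unanimous_ratify(self, game543, rng):
        """A formed outcome's final tentative must have been ratified by all."""
        outcome = run_alt_offers_game(game543, seated(OverbiddingAgent), rng)
        if outcome.status is Status.FORMED:
            ratifies = [
                e for e in outcome.events
                if e.action == "ratify" and e.chosen_entry == "RATIFY"
            ]
            members = outcome.coalition.members
            last_by_member = {}
            for e in outcome.events:
                if e.action == "ratify":
                    last_by_member[e.actor] = e.chosen_entry
            from coalsim.game import position_label

            assert all(
                last_by_member[position_label(m)] == "RATIFY" for m in members
            )

    def test_replay_determinism(self, game543):
        results = []
        for _ in range(2):
            agents = seated_agents("random", seed=3)
            outcome = run_alt_offers_game(
                game543, agents, np.random.default_rng(5)
            )
            results.append((outcome.record(), outcome.events))
        assert results[0] == results[1]
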