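"""Allocation rules: worked examples, brute-force agreement, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edsim.policies import (
    Allocation,
    QueueState,
    SBPConfig,
    alt_allocate,
    ifp_allocate,
    sbp_allocate,
)
from helpers import oracle_alt, oracle_ifp, oracle_sbp, random_queue_state


def make_state(d3, d4, df, rfree, t=200.0, joins3=None, joins4=None, joinsf=None):
    def q(n, joins):
        if joins is None:
            joins = [t - 50.0 + i for i in range(n)]
        return [(float(j), i) for i, j in enumerate(joins)]

    return QueueState(t, rfree, q(d3, joins3), q(d4, joins4), q(df, joinsf))


def takes(alloc: Allocation):
    return alloc.take3, alloc.take4, alloc.takef


class TestInitialFirst:
    @pytest.mark.parametrize(
        "demand, rfree, expect",
        [
            ((3, 4, 2), 5, (3, 2, 0)),
            ((0, 0, 4), 2, (0, 0, 2)),
            ((1, 0, 5), 1, (1, 0, 0)),  # follow-up starved while initial demand exists
        ],
    )
    def test_examples(self, demand, rfree, expect):
        assert takes(ifp_allocate(make_state(*demand, rfree))) == expect


class TestAlternating:
    def test_batch_quota_examples(self):
        alloc, toggle = alt_allocate(make_state(2, 3, 4, 5), True)
        assert takes(alloc) == (2, 0, 3)
        assert toggle is True  # toggle only used at single-server epochs
        alloc, _ = alt_allocate(make_state(0, 0, 4, 5), True)
        assert takes(alloc) == (0, 0, 4)  # redistribution cannot create demand

    def test_unused_followup_capacity_returns_to_initials(self):
        alloc, _ = alt_allocate(make_state(5, 2, 1, 6), True)
        # quota 3 initials (all Level III) + 1 follow-up, then the 2 spare
        # seats return to the leftover Level III demand
        assert takes(alloc) == (5, 0, 1)
        assert alloc.total == 6

    def test_single_server_alternation(self):
        state = make_state(1, 0, 1, 1)
        alloc, toggle = alt_allocate(state, True)
        assert takes(alloc) == (1, 0, 0) and toggle is False
        alloc, toggle = alt_allocate(state, toggle)
        assert takes(alloc) == (0, 0, 1) and toggle is True

    def test_single_server_single_category_keeps_toggle(self):
        alloc, toggle = alt_allocate(make_state(0, 0, 3, 1), True)
        assert takes(alloc) == (0, 0, 1) and toggle is True
        alloc, toggle = alt_allocate(make_state(0, 2, 0, 1), False)
        assert takes(alloc) == (0, 1, 0) and toggle is False


class TestSlackBased:
    CFG = SBPConfig(t3=30.0, t4=120.0, k1=13.1, k2=2.1)

    def test_urgency_boundary_is_inclusive(self):
        # wait exactly T3 - k1 = 16.9 -> urgent
        state = make_state(1, 0, 1, 1, t=100.0, joins3=[100.0 - 16.9], joinsf=[10.0])
        alloc = sbp_allocate(state, self.CFG)
        assert takes(alloc) == (1, 0, 0) and alloc.n3 == 1
        # a hair under the boundary -> follow-up outranks the non-urgent initial
        state = make_state(1, 0, 1, 1, t=100.0, joins3=[100.0 - 16.89], joinsf=[10.0])
        alloc = sbp_allocate(state, self.CFG)
        assert takes(alloc) == (0, 0, 1) and alloc.nr == 0

    def test_priority_hierarchy_counts(self):
        # |U3|=2, |U4|=1, |F|=3, |H|=2 (L3), R=5 -> (2, 1, 2, 0)
        t = 300.0
        state = QueueState(
            t,
            5,
            [(t - 20.0, 1), (t - 17.0, 2), (t - 5.0, 3), (t - 4.0, 4)],  # 2 urgent + 2 H
            [(t - 118.0, 5)],  # 1 urgent
            [(t - 30.0, 6), (t - 20.0, 7), (t - 10.0, 8)],
            )
        alloc = sbp_allocate(state, self.CFG)
        assert (alloc.n3, alloc.n4, alloc.nf, alloc.nr) == (2, 1, 2, 0)
        assert takes(alloc) == (2, 1, 2)

    def test_infinite_tolerance_reduces_to_initial_first(self):
        cfg = SBPConfig(30.0, 120.0, 1e12, 1e12)
        rng = np.random.default_rng(0)
        for _ in range(500):
            state = random_queue_state(rng)
            assert takes(sbp_allocate(state, cfg)) == takes(ifp_allocate(state))

    def test_zero_tolerance_infinite_target_puts_followups_first(self):
        cfg = SBPConfig(1e15, 1e15, 0.0, 0.0)
        rng = np.random.default_rng(1)
        for _ in range(500):
            state = random_queue_state(rng)
            n3, n4, nf = oracle_sbp(state, cfg)
            assert takes(sbp_allocate(state, cfg)) == (n3, n4, nf)
            assert nf == min(len(state.follow), state.rfree)


class TestBruteForceAgreement:
    """Exact match with explicit priority-ordered-list oracles on random states."""

    N = 10_000

    def test_initial_first(self):
        rng = np.random.default_rng(10)
        for _ in range(self.N):
            state = random_queue_state(rng)
            assert takes(ifp_allocate(state)) == oracle_ifp(state)

    def test_slack_based(self):
        rng = np.random.default_rng(11)
        for _ in range(self.N):
            state = random_queue_state(rng)
            k1, k2 = rng.uniform(0, 40, 2)
            cfg = SBPConfig(30.0, 120.0, float(k1), float(k2))
            assert takes(sbp_allocate(state, cfg)) == oracle_sbp(state, cfg)

    def test_alternating(self):
        rng = np.random.default_rng(12)
        toggle = True
        for _ in range(self.N):
            state = random_queue_state(rng)
            alloc, new_toggle = alt_allocate(state, toggle)
            expect, oracle_toggle = oracle_alt(state, toggle)
            assert takes(alloc) == expect
            assert new_toggle == oracle_toggle
            toggle = new_toggle


@st.composite
def queue_states(draw):
    t = 300.0
    def joins(n):
        return sorted(draw(st.lists(st.floats(0.0, 299.0), min_size=n, max_size=n)))
    n3, n4, nf = (draw(st.integers(0, 6)) for _ in range(3))
    return QueueState(
        t,
        draw(st.integers(1, 8)),
        [(j, 100 + i) for i, j in enumerate(joins(n3))],
        [(j, 200 + i) for i, j in enumerate(joins(n4))],
        [(j, 300 + i) for i, j in enumerate(joins(nf))],
    )


@settings(max_examples=300, deadline=None, derandomize=True)
@given(state=queue_states(), policy=st.sampled_from(["IFP", "ALT", "SBP"]),
       toggle=st.booleans(), k=st.floats(0.0, 40.0))
def test_allocation_invariants(state, policy, toggle, k):
    """No policy over-allocates, invents demand, or violates FIFO-prefix selection."""
    if policy == "IFP":
        alloc = ifp_allocate(state)
    elif policy == "ALT":
        alloc, _ = alt_allocate(state, toggle)
    else:
        alloc = sbp_allocate(state, SBPConfig(30.0, 120.0, k, k))
    d3, d4, df = state.demand
    assert alloc.total <= state.rfree
    assert 0 <= alloc.take3 <= d3 and 0 <= alloc.take4 <= d4 and 0 <= alloc.takef <= df
    # work conservation: all free physicians used whenever demand suffices
    assert alloc.total == min(state.rfree, d3 + d4 + df)
    # FIFO within class: selected ids are the queue heads
    assert alloc.init3_ids == [pid for _, pid in state.init3[: alloc.take3]]
    assert alloc.init4_ids == [pid for _, pid in state.init4[: alloc.take4]]
    assert alloc.follow_ids == [pid for _, pid in state.follow[: alloc.takef]]
    # reported category counts match the take totals
    assert alloc.n3 + alloc.n4 + alloc.nr == alloc.take3 + alloc.take4
    assert alloc.nf == alloc.takef
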