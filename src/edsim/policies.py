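"""Physician-allocation policies.

At a decision epoch the engine presents the three FIFO queues (Level III
initial, Level IV initial, follow-up) together with the number of free
physicians; a policy answers with how many patients to take from each queue.
Because every rule respects first-come-first-served within a class, a
selection is always a FIFO prefix of each queue, so per-class counts identify
the selected patients exactly.

Three rules are implemented:

* **IFP** (Initial-First): initial consultations always outrank follow-ups,
  Level III before Level IV.
* **ALT** (Alternating 1:1): at most half the free physicians go to initial
  consultations (Level III first), the rest to follow-ups; unused quota on
  either side is redistributed so no physician idles while anyone waits.
  When a single physician frees with both categories waiting, a toggle
  alternates initial/follow-up, realizing the 1:1 ratio one decision at a
  time.
* **SBP** (Slack-Based): an initial patient becomes *urgent* once its wait
  is within the slack tolerance of its clinical target (wait >= T_l - k_l,
  inclusive).  Priority order: urgent Level III > urgent Level IV >
  follow-ups > non-urgent initials (Level III before Level IV), FIFO within
  each set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .config import PolicySpec, TriageConfig

__all__ = [
    "QueueState",
    "Allocation",
    "SBPConfig",
    "Policy",
    "InitialFirstPolicy",
    "AlternatingPolicy",
    "SlackBasedPolicy",
    "make_policy",
    "ifp_allocate",
    "alt_allocate",
    "sbp_allocate",
]


@dataclass
class QueueState:
    """Queue snapshot at a decision epoch.

    Each queue is a FIFO sequence of ``(join_time, patient_id)`` pairs (oldest
    first); newly arrived patients at the epoch are already appended, so the
    sequences carry the full demand D per class.
    """

    t: float
    rfree: int
    init3: Sequence[tuple[float, int]]
    init4: Sequence[tuple[float, int]]
    follow: Sequence[tuple[float, int]]

    @property
    def demand(self) -> tuple[int, int, int]:
        return len(self.init3), len(self.init4), len(self.follow)


@dataclass
class SBPConfig:
    """Slack-based thresholds: clinical targets T3, T4 and tolerances k1, k2 (min)."""

    t3: float
    t4: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.t3 <= 0 or self.t4 <= 0:
            raise ValueError("clinical targets must be > 0")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("slack tolerances must be >= 0")


@dataclass
class Allocation:
    """A policy decision: per-class take counts plus selected identities.

    ``n3``/``n4`` are urgent counts and ``nr`` the non-urgent initial count
    under SBP; under IFP/ALT all initial selections are reported in
    ``n3``/``n4`` and ``nr`` is 0.  ``take3``/``take4``/``takef`` are the
    total numbers popped from each queue (FIFO prefixes).
    """

    take3: int = 0
    take4: int = 0
    takef: int = 0
    n3: int = 0
    n4: int = 0
    nf: int = 0
    nr: int = 0
    init3_ids: list[int] = field(default_factory=list)
    init4_ids: list[int] = field(default_factory=list)
    follow_ids: list[int] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.take3 + self.take4 + self.takef


def _prefix_ids(queue: Sequence[tuple[float, int]], n: int) -> list[int]:
    out = []
    for i, (_, pid) in enumerate(queue):
        if i >= n:
            break
        out.append(pid)
    return out


def _finish(state: QueueState, take3: int, take4: int, takef: int, n3: int, n4: int, nf: int, nr: int) -> Allocation:
    return Allocation(
        take3,
        take4,
        takef,
        n3,
        n4,
        nf,
        nr,
        _prefix_ids(state.init3, take3),
        _prefix_ids(state.init4, take4),
        _prefix_ids(state.follow, takef),
    )


def ifp_allocate(state: QueueState) -> Allocation:
    """Initial-First: N3 = min(D3, R); N4 = min(D4, R-N3); Nf = min(Df, rest)."""
    d3, d4, df = state.demand
    r = state.rfree
    n3 = min(d3, r)
    n4 = min(d4, r - n3)
    nf = min(df, r - n3 - n4)
    return _finish(state, n3, n4, nf, n3, n4, nf, 0)


def alt_allocate(state: QueueState, toggle_initial: bool) -> tuple[Allocation, bool]:
    """Alternating 1:1; returns the allocation and the updated toggle.

    With two or more free physicians the batch quota form applies: at most
    floor(R/2) initials (Level III first), the remainder to follow-ups, and
    any capacity still unused is redistributed to whichever category has
    leftover demand.  With exactly one free physician and both categories
    nonempty, the toggle decides which category is served and then flips;
    if only one category has demand it is served and the toggle is unchanged.
    """
    d3, d4, df = state.demand
    r = state.rfree
    if r == 1:
        if (d3 + d4) > 0 and df > 0:
            if toggle_initial:
                alloc = (
                    _finish(state, 1, 0, 0, 1, 0, 0, 0)
                    if d3
                    else _finish(state, 0, 1, 0, 0, 1, 0, 0)
                )
            else:
                alloc = _finish(state, 0, 0, 1, 0, 0, 1, 0)
            return alloc, not toggle_initial
        # single nonempty category: serve it, toggle unchanged
        if d3 + d4 > 0:
            n3 = min(d3, 1)
            return _finish(state, n3, 1 - n3 if d4 else 0, 0, n3, 1 - n3 if d4 else 0, 0, 0), toggle_initial
        if df > 0:
            return _finish(state, 0, 0, 1, 0, 0, 1, 0), toggle_initial
        return Allocation(), toggle_initial

    quota = r // 2
    n3 = min(d3, quota)
    n4 = min(d4, quota - n3)
    nf = min(df, r - n3 - n4)
    # redistribute unused capacity to leftover initial demand
    remaining = r - n3 - n4 - nf
    extra3 = min(d3 - n3, remaining)
    n3 += extra3
    remaining -= extra3
    extra4 = min(d4 - n4, remaining)
    n4 += extra4
    return _finish(state, n3, n4, nf, n3, n4, nf, 0), toggle_initial


def sbp_allocate(state: QueueState, cfg: SBPConfig) -> Allocation:
    """Slack-based: urgent L3 > urgent L4 > follow-ups > non-urgent initials.

    A Level-l patient is urgent when its wait satisfies w >= T_l - k_l
    (inclusive).  Waits are monotone along each FIFO queue, so the urgent
    members form a prefix of their queue.
    """
    t, r = state.t, state.rfree
    cutoff3 = t - (cfg.t3 - cfg.k1)  # join_time <= cutoff  <=>  wait >= T-k
    cutoff4 = t - (cfg.t4 - cfg.k2)
    u3 = _count_urgent(state.init3, cutoff3)
    u4 = _count_urgent(state.init4, cutoff4)
    d3, d4, df = state.demand
    n3 = min(u3, r)
    n4 = min(u4, r - n3)
    nf = min(df, r - n3 - n4)
    rem = r - n3 - n4 - nf
    h3 = min(d3 - u3, rem)  # non-urgent initials, Level III first
    h4 = min(d4 - u4, rem - h3)
    return _finish(state, n3 + h3, n4 + h4, nf, n3, n4, nf, h3 + h4)


def _count_urgent(queue: Sequence[tuple[float, int]], cutoff: float) -> int:
    n = 0
    for join, _ in queue:
        if join <= cutoff:
            n += 1
        else:
            break
    return n


class Policy:
    """Stateful policy wrapper used by the engine (one instance per replication)."""

    name: str = "?"

    def reset(self) -> None:  # pragma: no cover - trivial default
        """Clear any per-replication state before a fresh run."""

    def allocate(self, state: QueueState) -> Allocation:
        raise NotImplementedError


class InitialFirstPolicy(Policy):
    name = "IFP"

    def allocate(self, state: QueueState) -> Allocation:
        return ifp_allocate(state)


class AlternatingPolicy(Policy):
    name = "ALT"

    def __init__(self) -> None:
        self.toggle_initial = True

    def reset(self) -> None:
        self.toggle_initial = True

    def allocate(self, state: QueueState) -> Allocation:
        alloc, self.toggle_initial = alt_allocate(state, self.toggle_initial)
        return alloc


class SlackBasedPolicy(Policy):
    name = "SBP"

    def __init__(self, cfg: SBPConfig) -> None:
        self.cfg = cfg

    def allocate(self, state: QueueState) -> Allocation:
        return sbp_allocate(state, self.cfg)


def make_policy(spec: PolicySpec, triage: TriageConfig) -> Policy:
    """Instantiate a policy from its scenario spec (SBP targets come from triage)."""
    if spec.name == "IFP":
        return InitialFirstPolicy()
    if spec.name == "ALT":
        return AlternatingPolicy()
    return SlackBasedPolicy(
        SBPConfig(triage.target_wait[3], triage.target_wait[4], spec.k1, spec.k2)
    )
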