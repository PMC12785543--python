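"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np

from edsim.config import (
    ArrivalSchedule,
    ConsultationTimeConfig,
    ExamConfig,
    ExamModality,
    PolicySpec,
    ScenarioConfig,
    Shift,
    StaffingSchedule,
    TriageConfig,
)
from edsim.policies import QueueState, SBPConfig


def near_constant_service(kind: str, minutes: float) -> ConsultationTimeConfig:
    """A consultation distribution pinched to an (almost) deterministic value."""
    eps = 1e-7
    return ConsultationTimeConfig(kind, "truncexp", minutes, minutes - eps, minutes + eps)


def exam_config(p_exam: float = 0.0, **probs) -> ExamConfig:
    """Baseline-shaped exam subsystem with overridable requirement probabilities."""
    base = {
        "laboratory": ExamModality(probs.get("laboratory", 0.92), 1.19, 20.0, 1),
        "ultrasound": ExamModality(probs.get("ultrasound", 0.22), 6.58, 0.0, 1),
        "xray": ExamModality(probs.get("xray", 0.29), 3.99, 30.0, 1),
        "ct": ExamModality(probs.get("ct", 0.55), probs.get("ct_tau", 2.45), 30.0, 1),
    }
    return ExamConfig(p_exam=p_exam, modalities=base)


def simple_scenario(
    physicians: int = 1,
    rate: float = 0.0,
    p_level3: float = 0.0,
    service_min: float = 10.0,
    follow_min: float = 10.0,
    exams: ExamConfig | None = None,
    policy: PolicySpec = PolicySpec("IFP"),
    horizon: float = 1440.0,
) -> ScenarioConfig:
    """Single-shift micro scenario for hand-traceable engine tests."""
    return ScenarioConfig(
        arrivals=ArrivalSchedule(np.full((7, 24), rate)),
        triage=TriageConfig(p_level3=p_level3),
        consult_initial=near_constant_service("initial", service_min),
        consult_followup=near_constant_service("follow_up", follow_min),
        exams=exams if exams is not None else exam_config(0.0),
        staffing=StaffingSchedule((Shift(0, 1440, physicians),)),
        policy=policy,
        horizon=horizon,
        n_reps=1,
        base_seed=1,
    )


def mmc_scenario(lam_per_hr: float, mean_svc: float, c: int) -> ScenarioConfig:
    """Constant-rate, single-class, no-exam scenario: an M/M/c queue.

    The service truncation window [1e-9, 1e6] leaves the exponential
    effectively untruncated.
    """
    return ScenarioConfig(
        arrivals=ArrivalSchedule(np.full((7, 24), lam_per_hr)),
        triage=TriageConfig(p_level3=1.0),
        consult_initial=ConsultationTimeConfig("initial", "truncexp", mean_svc, 1e-9, 1e6),
        consult_followup=ConsultationTimeConfig("follow_up", "truncexp", 15.0, 5.0, 25.0),
        exams=exam_config(0.0),
        staffing=StaffingSchedule((Shift(0, 1440, c),)),
        policy=PolicySpec("IFP"),
        horizon=10080.0,
        n_reps=1,
        base_seed=1,
    )


def erlang_c_mean_wait(lam: float, mu: float, c: int) -> float:
    """Closed-form M/M/c mean queue wait (Erlang-C), times in minutes."""
    a = lam / mu
    rho = a / c
    if rho >= 1:
        raise ValueError("unstable queue")
    s = sum(a**k / math.factorial(k) for k in range(c))
    tail = a**c / math.factorial(c) / (1 - rho)
    prob_wait = tail / (s + tail)
    return prob_wait / (c * mu - lam)


# ---------------------------------------------------------------------------
# Brute-force allocation oracles: build the explicit priority-ordered patient
# list, take the first Rfree, and count per queue.

def oracle_ifp(state: QueueState) -> tuple[int, int, int]:
    ordered = (
        [("init3", p) for p in state.init3]
        + [("init4", p) for p in state.init4]
        + [("follow", p) for p in state.follow]
    )
    return _take(ordered, state.rfree)


def oracle_sbp(state: QueueState, cfg: SBPConfig) -> tuple[int, int, int]:
    u3 = [p for p in state.init3 if state.t - p[0] >= cfg.t3 - cfg.k1]
    h3 = [p for p in state.init3 if state.t - p[0] < cfg.t3 - cfg.k1]
    u4 = [p for p in state.init4 if state.t - p[0] >= cfg.t4 - cfg.k2]
    h4 = [p for p in state.init4 if state.t - p[0] < cfg.t4 - cfg.k2]
    ordered = (
        [("init3", p) for p in u3]
        + [("init4", p) for p in u4]
        + [("follow", p) for p in state.follow]
        + [("init3", p) for p in h3]
        + [("init4", p) for p in h4]
    )
    return _take(ordered, state.rfree)


def oracle_alt(state: QueueState, toggle_initial: bool) -> tuple[tuple[int, int, int], bool]:
    """Independent re-statement of the alternating rule (quota + redistribution,
    single-server toggle), coded from the written rule rather than shared code."""
    d3, d4, df = len(state.init3), len(state.init4), len(state.follow)
    r = state.rfree
    if r == 1:
        if (d3 + d4) > 0 and df > 0:
            if toggle_initial:
                out = (1, 0, 0) if d3 > 0 else (0, 1, 0)
            else:
                out = (0, 0, 1)
            return out, not toggle_initial
        if d3 > 0:
            return (1, 0, 0), toggle_initial
        if d4 > 0:
            return (0, 1, 0), toggle_initial
        if df > 0:
            return (0, 0, 1), toggle_initial
        return (0, 0, 0), toggle_initial
    quota = r // 2
    n3 = min(d3, quota)
    n4 = min(d4, max(0, quota - n3))
    nf = min(df, r - n3 - n4)
    while n3 + n4 + nf < r and (n3 < d3 or n4 < d4):
        if n3 < d3:
            n3 += 1
        else:
            n4 += 1
    return (n3, n4, nf), toggle_initial


def _take(ordered, r: int) -> tuple[int, int, int]:
    counts = {"init3": 0, "init4": 0, "follow": 0}
    for q, _ in ordered[:r]:
        counts[q] += 1
    return counts["init3"], counts["init4"], counts["follow"]


def random_queue_state(rng: np.random.Generator, t: float = 200.0) -> QueueState:
    """Random FIFO queue snapshot with plausible join times."""
    def queue(max_len=6, max_age=250.0):
        n = int(rng.integers(0, max_len + 1))
        joins = np.sort(t - rng.uniform(0.0, max_age, n))
        return [(float(j), int(1000 + rng.integers(0, 1000))) for j in joins]

    return QueueState(
        t=t,
        rfree=int(rng.integers(1, 7)),
        init3=queue(),
        init4=queue(),
        follow=queue(),
    )
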