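"""Event-calendar simulation core.

The engine advances an event heap over arrivals, consultation completions,
exam processing completions, report readiness, and shift changes on
``[0, horizon)``.  Patients flow

    arrival -> initial queue -> initial consult -> (if required) exams
            -> follow-up queue -> follow-up consult -> exit

A scheduling decision is taken whenever a physician frees (consult end, or an
upward shift boundary) and whenever an arrival or a newly exam-complete
patient meets idle capacity.  Consultations are never preempted; physicians
caught mid-consult by a downward shift boundary finish the current patient
and then withdraw ("lame duck").

All randomness is pre-generated per replication from four named substreams
(arrival counts/instants, triage levels, consult durations, exam
requirements) keyed only by the replication seed, so two policies run with
the same seed see *identical* patient material — exact common random numbers.

Event ties at equal times resolve consult_end < exam_end < report_ready <
shift_change < arrival, then by insertion sequence, so freed physicians are
available to same-instant arrivals and runs are bit-reproducible.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arrivals import ArrivalEventList, assign_levels, generate_arrivals
from .config import MODALITIES, ScenarioConfig
from .policies import Policy, QueueState, make_policy
from .sampling import exam_order, sample_consult_durations, sample_exam_requirements_batch, ExamRequirement

__all__ = ["PatientRecord", "ExamVisit", "EpochLogEntry", "ReplicationResult", "run_replication", "run_experiment"]

# event type priorities (tie-break order at equal times)
_EV_CONSULT_END = 0
_EV_EXAM_END = 1
_EV_REPORT_READY = 2
_EV_SHIFT = 3
_EV_ARRIVAL = 4


@dataclass
class ExamVisit:
    """One exam on one device: ready/start/processing-end/report-ready times."""

    modality: str
    ready: float
    start: float = np.nan
    proc_end: float = np.nan
    report_ready: float = np.nan

    @property
    def extra_delay(self) -> float:
        """Queueing delay rho incurred because the device was busy."""
        return self.start - self.ready


@dataclass
class PatientRecord:
    """Full timestamp trail of one patient."""

    id: int
    arrival: float
    level: int
    init_start: float = np.nan
    init_end: float = np.nan
    needs_exam: bool = False
    exams: list[ExamVisit] = field(default_factory=list)
    t_exam: float = np.nan  # all reports available
    follow_join: float = np.nan
    follow_start: float = np.nan
    follow_end: float = np.nan

    @property
    def init_wait(self) -> float:
        return self.init_start - self.arrival

    @property
    def follow_wait(self) -> float:
        return self.follow_start - self.follow_join

    @property
    def completed_initial(self) -> bool:
        return not np.isnan(self.init_end)

    @property
    def completed_followup(self) -> bool:
        return not np.isnan(self.follow_end)

    @property
    def completed_pathway(self) -> bool:
        """Finished everything required of them (incl. follow-up if exams)."""
        if not self.completed_initial:
            return False
        return self.completed_followup if self.needs_exam else True

    @property
    def total_wait(self) -> float:
        """Cumulative waiting over the whole completed pathway."""
        w = self.init_wait
        if self.needs_exam:
            w += self.follow_wait
        return w


@dataclass
class EpochLogEntry:
    """Queue bookkeeping at one decision epoch (for conservation checks)."""

    t: float
    rfree: int
    before: tuple[int, int, int]  # queue lengths incl. new joins, per class
    inflow: tuple[int, int, int]  # joins since the previous epoch
    allocated: tuple[int, int, int]


@dataclass
class ReplicationResult:
    """Everything one replication produced."""

    scenario_hash: str
    policy: str
    seed: int
    horizon: float
    records: list[PatientRecord]
    physician_busy_min: float
    scheduled_physician_min: float
    device_busy_min: dict[str, float]
    n_arrivals: int
    epoch_log: list[EpochLogEntry] | None = None

    def trail_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.id,
                    "arrival": r.arrival,
                    "level": r.level,
                    "init_start": r.init_start,
                    "init_end": r.init_end,
                    "needs_exam": r.needs_exam,
                    "t_exam": r.t_exam,
                    "follow_join": r.follow_join,
                    "follow_start": r.follow_start,
                    "follow_end": r.follow_end,
                }
            )
        return pd.DataFrame(rows)

    def trail_to_csv(self, path: str | Path) -> None:
        self.trail_dataframe().to_csv(path, index=False)


class _DeviceBank:
    """FIFO device queues per modality with integer capacities."""

    __slots__ = ("free", "queue")

    def __init__(self, capacities: dict[str, int]):
        self.free = dict(capacities)
        self.queue: dict[str, list] = {m: [] for m in capacities}


def _spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    arr, lev, serv, exam = ss.spawn(4)
    return {
        "arrivals": np.random.default_rng(arr),
        "levels": np.random.default_rng(lev),
        "services": np.random.default_rng(serv),
        "exams": np.random.default_rng(exam),
    }


def run_replication(
    config: ScenarioConfig,
    policy: Policy | str | None = None,
    seed: int | None = None,
    arrivals: ArrivalEventList | None = None,
    record_epochs: bool = False,
) -> ReplicationResult:
    """Simulate one week (one ``config.horizon``) and return the full trail.

    ``policy`` may be a :class:`~edsim.policies.Policy` instance, a policy
    name ("IFP"/"ALT"/"SBP" — SBP thresholds then come from the scenario's
    policy spec), or None to use the scenario's configured policy.
    ``arrivals`` replaces the stochastic arrival stream with a scripted one
    (replay mode); levels then come from the script, not the level stream.
    Deterministic given (config, policy, seed).
    """
    if seed is None:
        seed = config.base_seed
    if policy is None or isinstance(policy, str):
        spec = config.policy if policy is None else _spec_for(config, policy)
        policy = make_policy(spec, config.triage)
    policy.reset()
    streams = _spawn_streams(seed)

    horizon = float(config.horizon)
    if arrivals is None:
        times, _ = generate_arrivals(
            config.arrivals, horizon, config.arrival_scale, streams["arrivals"]
        )
        levels = assign_levels(streams["levels"], config.triage, times.size)
    else:
        times, levels = arrivals.times, arrivals.levels
    n = int(times.size)

    # pre-generate patient material (policy-independent: exact CRN)
    init_dur = sample_consult_durations(config.consult_initial, streams["services"], n)
    follow_dur = sample_consult_durations(config.consult_followup, streams["services"], n)
    exam_flags = sample_exam_requirements_batch(config.exams, streams["exams"], n)
    mod_index = {m: j for j, m in enumerate(MODALITIES)}
    tau = {m: config.exams.modalities[m].processing_time for m in MODALITIES}
    delta = {m: config.exams.modalities[m].report_delay for m in MODALITIES}

    records = [PatientRecord(i, float(times[i]), int(levels[i])) for i in range(n)]
    exam_orders: list[tuple[str, ...]] = [()] * n
    for i in range(n):
        if exam_flags[i].any():
            records[i].needs_exam = True
            req = ExamRequirement({m: bool(exam_flags[i][mod_index[m]]) for m in MODALITIES})
            exam_orders[i] = exam_order(req, config.exams)

    # event heap: (time, type_priority, seq, payload)
    heap: list[tuple[float, int, int, tuple]] = []
    seq = 0

    def push(t: float, prio: int, payload: tuple) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, prio, seq, payload))
        seq += 1

    for i in range(n):
        push(float(times[i]), _EV_ARRIVAL, ("arr", i))
    day_changes = config.staffing.change_points()
    for day in range(int(horizon // 1440)):
        for minute, count in day_changes:
            t = day * 1440.0 + minute
            if 0.0 < t < horizon:
                push(t, _EV_SHIFT, ("shift", count))

    # live state
    q3: list[tuple[float, int]] = []
    q4: list[tuple[float, int]] = []
    qf: list[tuple[float, int]] = []
    # pop pointers to avoid O(n) list.pop(0)
    h3 = h4 = hf = 0
    capacity = config.staffing.physicians_at(0.0)
    busy = 0
    phys_busy = 0.0
    devices = _DeviceBank({m: config.exams.modalities[m].capacity for m in MODALITIES})
    dev_busy = {m: 0.0 for m in MODALITIES}
    next_exam_idx = [0] * n  # position in the patient's exam order
    pending_exams = [0] * n  # exams not yet processing-complete
    epoch_log: list[EpochLogEntry] | None = [] if record_epochs else None
    inflow = [0, 0, 0]

    def start_exam(i: int, m: str, t: float) -> None:
        nonlocal seq
        visit = records[i].exams[-1]
        visit.start = t
        visit.proc_end = t + tau[m]
        visit.report_ready = visit.proc_end + delta[m]
        dev_busy[m] += max(0.0, min(visit.proc_end, horizon) - min(t, horizon))
        push(visit.proc_end, _EV_EXAM_END, ("exam_end", i, m))

    def request_exam(i: int, t: float) -> None:
        """Patient i becomes ready for their next exam at time t."""
        m = exam_orders[i][next_exam_idx[i]]
        records[i].exams.append(ExamVisit(m, t))
        if devices.free[m] > 0:
            devices.free[m] -= 1
            start_exam(i, m, t)
        else:
            devices.queue[m].append(i)

    def dispatch(t: float) -> None:
        nonlocal busy, h3, h4, hf, phys_busy, inflow
        idle = capacity - busy
        if idle <= 0:
            return
        v3 = q3[h3:]
        v4 = q4[h4:]
        vf = qf[hf:]
        if not (v3 or v4 or vf):
            return
        state = QueueState(t, idle, v3, v4, vf)
        alloc = policy.allocate(state)
        if epoch_log is not None:
            epoch_log.append(
                EpochLogEntry(
                    t,
                    idle,
                    (len(v3), len(v4), len(vf)),
                    tuple(inflow),
                    (alloc.take3, alloc.take4, alloc.takef),
                )
            )
            inflow = [0, 0, 0]
        for _ in range(alloc.take3):
            _start_consult(q3[h3][1], t, "initial")
            h3 += 1
        for _ in range(alloc.take4):
            _start_consult(q4[h4][1], t, "initial")
            h4 += 1
        for _ in range(alloc.takef):
            _start_consult(qf[hf][1], t, "follow")
            hf += 1
        # compact the queue lists occasionally
        if h3 > 512:
            del q3[:h3]
            h3 = 0
        if h4 > 512:
            del q4[:h4]
            h4 = 0
        if hf > 512:
            del qf[:hf]
            hf = 0

    def _start_consult(i: int, t: float, kind: str) -> None:
        nonlocal busy, phys_busy
        rec = records[i]
        if kind == "initial":
            rec.init_start = t
            dur = init_dur[i]
        else:
            rec.follow_start = t
            dur = follow_dur[i]
        end = t + float(dur)
        busy += 1
        phys_busy += min(end, horizon) - t
        if end < horizon:
            push(end, _EV_CONSULT_END, ("consult_end", i, kind))
        # a consult ending at/after the horizon never completes: censored

    while heap:
        t, prio, _, payload = heapq.heappop(heap)
        if t >= horizon:
            break
        tag = payload[0]
        if tag == "consult_end":
            _, i, kind = payload
            busy -= 1
            rec = records[i]
            if kind == "initial":
                rec.init_end = t
                if rec.needs_exam:
                    request_exam(i, t)
            else:
                rec.follow_end = t
            dispatch(t)
        elif tag == "exam_end":
            _, i, m = payload
            devices.free[m] += 1
            if devices.queue[m]:
                nxt = devices.queue[m].pop(0)
                devices.free[m] -= 1
                start_exam(nxt, m, t)
            next_exam_idx[i] += 1
            if next_exam_idx[i] < len(exam_orders[i]):
                request_exam(i, t)
            else:
                t_exam = max(v.report_ready for v in records[i].exams)
                records[i].t_exam = t_exam
                push(t_exam, _EV_REPORT_READY, ("follow_ready", i))
        elif tag == "follow_ready":
            _, i = payload
            records[i].follow_join = t
            qf.append((t, i))
            inflow[2] += 1
            if capacity - busy > 0:
                dispatch(t)
        elif tag == "shift":
            _, count = payload
            increased = count > capacity
            capacity = count
            if increased:
                dispatch(t)
        elif tag == "arr":
            _, i = payload
            if records[i].level == 3:
                q3.append((t, i))
                inflow[0] += 1
            else:
                q4.append((t, i))
                inflow[1] += 1
            if capacity - busy > 0:
                dispatch(t)

    return ReplicationResult(
        scenario_hash=config.scenario_hash(),
        policy=policy.name,
        seed=seed,
        horizon=horizon,
        records=records,
        physician_busy_min=phys_busy,
        scheduled_physician_min=config.staffing.scheduled_minutes(horizon),
        device_busy_min=dev_busy,
        n_arrivals=n,
        epoch_log=epoch_log,
    )


def _spec_for(config: ScenarioConfig, name: str):
    from .config import PolicySpec

    if name == "SBP":
        if config.policy.name == "SBP":
            return config.policy
        raise ValueError("running SBP by name requires SBP thresholds in the scenario")
    return PolicySpec(name)


def run_experiment(
    config: ScenarioConfig,
    policy: Policy | str | None = None,
    n_reps: int | None = None,
    base_seed: int | None = None,
    record_epochs: bool = False,
) -> list[ReplicationResult]:
    """Run ``n_reps`` independent replications; replication r uses seed
    ``base_seed + r``.  Running two policies with the same ``base_seed``
    reuses identical random streams (common random numbers)."""
    n_reps = config.n_reps if n_reps is None else n_reps
    base_seed = config.base_seed if base_seed is None else base_seed
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return [
        run_replication(config, policy, base_seed + r, record_epochs=record_epochs)
        for r in range(n_reps)
    ]
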