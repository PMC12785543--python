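"""KPIs per replication and aggregation across replications.

Waiting-time KPIs come in two layers:

* *Stage waits* — initial wait (arrival to initial-consult start) per level,
  and follow-up wait (all reports available to follow-up-consult start); the
  record-pooled mean ``w_total_records`` pools every stage-wait record (an
  exam patient contributes two records).
* *Patient waits* — each fully completed patient's cumulative waiting
  (initial wait plus, for exam patients, follow-up wait), reported per level
  (``w_level3``/``w_level4``) and overall (``w_overall``).  These are the
  headline waiting-time statistics: the per-level figure answers "how long
  does a Level-l patient spend waiting in total", and the overall figure is
  their patient-weighted average.

Delay rates and service levels are defined on *initial* waits against the
clinical targets (strictly greater than the target counts as a delay; a wait
exactly at the target is on time).  Patients still in the system at the
horizon are censored: they contribute no wait records, but busy time they
generated does count toward utilization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .config import MODALITIES, ScenarioConfig, TriageConfig
from .engine import ReplicationResult

__all__ = [
    "WaitingTimes",
    "ReplicationMetrics",
    "waiting_times",
    "delay_and_service",
    "utilization",
    "summarize",
    "aggregate",
    "ci_normal",
]

Z_95 = 1.96


@dataclass
class WaitingTimes:
    """Stage-wait records and the derived means for one replication."""

    init3: np.ndarray
    init4: np.ndarray
    follow: np.ndarray
    level3_total: np.ndarray  # cumulative per completed Level-III patient
    level4_total: np.ndarray

    @property
    def w_init3(self) -> float:
        return float(np.mean(self.init3)) if self.init3.size else math.nan

    @property
    def w_init4(self) -> float:
        return float(np.mean(self.init4)) if self.init4.size else math.nan

    @property
    def w_follow(self) -> float:
        return float(np.mean(self.follow)) if self.follow.size else math.nan

    @property
    def w_total_records(self) -> float:
        """Pool every stage-wait record across the three classes."""
        total = self.init3.size + self.init4.size + self.follow.size
        if total == 0:
            return math.nan
        s = self.init3.sum() + self.init4.sum() + self.follow.sum()
        return float(s / total)

    @property
    def w_level3(self) -> float:
        return float(np.mean(self.level3_total)) if self.level3_total.size else math.nan

    @property
    def w_level4(self) -> float:
        return float(np.mean(self.level4_total)) if self.level4_total.size else math.nan

    @property
    def w_overall(self) -> float:
        n = self.level3_total.size + self.level4_total.size
        if n == 0:
            return math.nan
        return float((self.level3_total.sum() + self.level4_total.sum()) / n)


def waiting_times(result: ReplicationResult) -> WaitingTimes:
    """Extract stage and cumulative waits from a finished replication.

    Only completed consultations contribute: an initial (follow-up) wait is
    recorded iff that consult finished inside the horizon, and a patient's
    cumulative wait is recorded iff their whole pathway completed.
    """
    init3, init4, follow = [], [], []
    lvl_tot: dict[int, list[float]] = {3: [], 4: []}
    for r in result.records:
        if r.completed_initial:
            (init3 if r.level == 3 else init4).append(r.init_wait)
        if r.completed_followup:
            follow.append(r.follow_wait)
        if r.completed_pathway:
            lvl_tot[r.level].append(r.total_wait)
    return WaitingTimes(
        np.asarray(init3),
        np.asarray(init4),
        np.asarray(follow),
        np.asarray(lvl_tot[3]),
        np.asarray(lvl_tot[4]),
    )


def delay_and_service(
    result: ReplicationResult, triage: TriageConfig
) -> dict[str, float]:
    """Delay rates Delta_l (share of initial waits strictly above T_l) and
    service levels SL_l = 1 - Delta_l, as proportions in [0, 1]."""
    wt = waiting_times(result)
    out: dict[str, float] = {}
    for level, waits in ((3, wt.init3), (4, wt.init4)):
        t_l = triage.target_wait[level]
        if waits.size == 0:
            delta = math.nan
        else:
            delta = float(np.mean(waits > t_l))
        out[f"delay{level}"] = delta
        out[f"sl{level}"] = 1.0 - delta if not math.isnan(delta) else math.nan
    return out


def utilization(result: ReplicationResult, config: ScenarioConfig) -> dict[str, float]:
    """Physician and device utilizations (busy time / available time)."""
    scheduled = result.scheduled_physician_min
    u_doc = result.physician_busy_min / scheduled if scheduled > 0 else math.nan
    out = {"u_doc": u_doc}
    for m in MODALITIES:
        cap = config.exams.modalities[m].capacity
        out[f"u_{m}"] = result.device_busy_min[m] / (cap * result.horizon)
    return out


@dataclass
class ReplicationMetrics:
    """Flat per-replication KPI vector."""

    w_init3: float
    w_init4: float
    w_follow: float
    w_total_records: float
    w_level3: float
    w_level4: float
    w_overall: float
    delay3: float
    delay4: float
    sl3: float
    sl4: float
    u_doc: float
    u_laboratory: float
    u_ultrasound: float
    u_xray: float
    u_ct: float
    n_arrivals: int
    n_completed_init3: int
    n_completed_init4: int
    n_completed_follow: int

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


def summarize(result: ReplicationResult, config: ScenarioConfig) -> ReplicationMetrics:
    wt = waiting_times(result)
    ds = delay_and_service(result, config.triage)
    ut = utilization(result, config)
    return ReplicationMetrics(
        w_init3=wt.w_init3,
        w_init4=wt.w_init4,
        w_follow=wt.w_follow,
        w_total_records=wt.w_total_records,
        w_level3=wt.w_level3,
        w_level4=wt.w_level4,
        w_overall=wt.w_overall,
        delay3=ds["delay3"],
        delay4=ds["delay4"],
        sl3=ds["sl3"],
        sl4=ds["sl4"],
        u_doc=ut["u_doc"],
        u_laboratory=ut["u_laboratory"],
        u_ultrasound=ut["u_ultrasound"],
        u_xray=ut["u_xray"],
        u_ct=ut["u_ct"],
        n_arrivals=result.n_arrivals,
        n_completed_init3=int(wt.init3.size),
        n_completed_init4=int(wt.init4.size),
        n_completed_follow=int(wt.follow.size),
    )


def metrics_frame(metrics: list[ReplicationMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.as_series() for m in metrics])


def ci_normal(mean: float, sd: float, n: int, z: float = Z_95) -> tuple[float, float]:
    """Normal-approximation confidence interval mean +/- z * sd / sqrt(n)."""
    half = z * sd / math.sqrt(n)
    return mean - half, mean + half


def aggregate(metrics: list[ReplicationMetrics] | pd.DataFrame) -> pd.DataFrame:
    """Across-replication mean, sample SD, min/max/median and 95% CI per KPI."""
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    if len(df) < 2:
        raise ValueError("aggregation requires at least 2 replications")
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1),
            "min": df.min(),
            "max": df.max(),
            "median": df.median(),
        }
    )
    n = len(df)
    half = Z_95 * out["sd"] / math.sqrt(n)
    out["ci_lo"] = out["mean"] - half
    out["ci_hi"] = out["mean"] + half
    out["n"] = n
    return out
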