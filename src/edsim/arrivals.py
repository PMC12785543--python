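"""Weekly-cyclic non-homogeneous Poisson arrivals and triage-level assignment.

The arrival process is piecewise constant at the hourly level: within hour
``h`` of day ``d`` the count is Poisson with mean ``scale * rates[d][h]`` and,
conditional on the count, arrival instants are i.i.d. uniform on the hour —
exactly the conditional law of a homogeneous Poisson process given its count,
so the construction is distributionally a non-homogeneous Poisson process
with the stated piecewise-constant intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ArrivalSchedule, TriageConfig

__all__ = ["ArrivalEventList", "rate_at", "generate_arrivals", "assign_level", "assign_levels"]


@dataclass
class ArrivalEventList:
    """Time-ordered arrivals: parallel arrays of times (min), ids, and levels."""

    times: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.times.shape != self.levels.shape:
            raise ValueError("times and levels must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("arrival times must be nondecreasing")
        if self.times.size and (self.times[0] < 0):
            raise ValueError("arrival times must be >= 0")
        if not np.all(np.isin(self.levels, (3, 4))):
            raise ValueError("triage levels must be 3 or 4")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "patient_id": self.ids, "level": self.levels}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ArrivalEventList":
        """Replay reader for scripted deterministic arrival files."""
        df = pd.read_csv(path)
        for col in ("time_min", "level"):
            if col not in df.columns:
                raise ValueError(f"arrival replay file missing column {col!r}")
        df = df.sort_values("time_min", kind="stable")
        return cls(df["time_min"].to_numpy(float), df["level"].to_numpy(int))


def rate_at(schedule: ArrivalSchedule, t: float, scale: float = 1.0) -> float:
    """Arrival rate (patients/hour) in force at simulation time ``t`` minutes.

    The day-of-week index is ``floor(t/1440) mod 7`` (day 0 = Monday, the
    clock starts Monday 00:00) and the hour-of-day index is
    ``floor((t mod 1440)/60)``.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    d = int(t // 1440) % 7
    h = int((t % 1440) // 60)
    return float(scale * schedule.rates[d, h])


def generate_arrivals(
    schedule: ArrivalSchedule,
    horizon: float,
    scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample arrival times on [0, horizon) and per-hour counts.

    Returns ``(times, hour_counts)`` where ``times`` is globally sorted and
    ``hour_counts[b]`` is the Poisson count of hour block ``b``.  Patient ids
    are positional (time order); ties keep generation order via stable sort.
    """
    horizon = float(horizon)
    if horizon <= 0 or horizon % 60 != 0:
        raise ValueError("horizon must be a positive multiple of 60 minutes")
    n_blocks = int(horizon // 60)
    block_starts = np.arange(n_blocks) * 60.0
    rates = np.array(
        [rate_at(schedule, t0, scale) for t0 in block_starts], dtype=float
    )
    counts = rng.poisson(rates)
    total = int(counts.sum())
    times = np.empty(total, dtype=float)
    pos = 0
    for b in range(n_blocks):
        c = int(counts[b])
        if c:
            u = rng.random(c)
            u.sort(kind="stable")
            times[pos : pos + c] = block_starts[b] + 60.0 * u
            pos += c
    return times, counts


def assign_level(rng: np.random.Generator, triage: TriageConfig) -> int:
    """Draw one triage level: 3 with probability Pr(3), else 4."""
    return 3 if rng.random() < triage.p_level3 else 4


def assign_levels(
    rng: np.random.Generator, triage: TriageConfig, n: int
) -> np.ndarray:
    """Vectorized :func:`assign_level` for ``n`` patients in arrival order."""
    return np.where(rng.random(n) < triage.p_level3, 3, 4).astype(np.int64)
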