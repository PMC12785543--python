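"""Scenario parameterization for the emergency-department simulator.

A scenario bundles everything one simulated ED "world" needs: the weekly
arrival-rate table, the triage mix and clinical wait targets, the two
consultation-time distributions, the diagnostic-examination subsystem, the
physician shift roster, the scheduling policy, and run settings (horizon,
replications, base seed).  All times are minutes; arrival rates are
patients per hour.  Scenarios serialize to a documented YAML schema and the
arrival table round-trips through CSV (columns Mon..Sun, 24 hourly rows).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MODALITIES",
    "DAY_NAMES",
    "SchemaError",
    "ValidationError",
    "ArrivalSchedule",
    "TriageConfig",
    "ConsultationTimeConfig",
    "ExamModality",
    "ExamConfig",
    "Shift",
    "StaffingSchedule",
    "PolicySpec",
    "ScenarioConfig",
    "default_baseline",
    "load_scenario",
    "save_scenario",
]

#: Canonical modality order (also the final tie-break in exam ordering).
MODALITIES = ("laboratory", "ultrasound", "xray", "ct")

DAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

MINUTES_PER_DAY = 1440
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY


class SchemaError(ValueError):
    """A scenario file is missing a field or has one of the wrong shape/type."""


class ValidationError(ValueError):
    """A structurally well-formed scenario violates a model invariant."""


# ---------------------------------------------------------------------------
# Weekly arrival-rate baseline: hourly rates (patients/hour), hours 0-23 by
# row, days Mon..Sun by column.
_BASELINE_RATES_HOUR_BY_DAY = [
    [7.84, 7.50, 7.51, 7.49, 7.49, 7.13, 7.12],
    [5.79, 5.37, 5.38, 5.35, 5.36, 5.07, 5.06],
    [4.94, 4.50, 4.51, 4.50, 4.49, 4.31, 4.32],
    [3.70, 3.33, 3.34, 3.30, 3.34, 3.11, 3.12],
    [2.19, 1.83, 1.81, 1.80, 1.82, 1.68, 1.68],
    [4.33, 3.58, 3.59, 3.54, 3.55, 3.21, 3.19],
    [6.78, 6.39, 6.40, 6.37, 6.36, 6.08, 6.07],
    [8.83, 8.23, 8.17, 8.18, 8.25, 7.98, 7.97],
    [15.23, 14.95, 14.93, 14.90, 14.90, 14.49, 14.48],
    [21.59, 21.26, 21.24, 21.23, 21.27, 20.64, 20.61],
    [21.71, 21.44, 21.43, 21.45, 21.43, 20.65, 20.64],
    [17.53, 17.11, 17.12, 17.11, 17.10, 16.59, 16.51],
    [15.55, 15.18, 15.17, 15.18, 15.17, 14.73, 14.72],
    [18.26, 17.93, 17.94, 17.92, 17.92, 17.43, 17.41],
    [20.87, 20.76, 20.77, 20.75, 20.77, 19.97, 19.96],
    [18.28, 18.14, 18.15, 18.13, 18.13, 17.33, 17.35],
    [17.31, 17.14, 17.15, 17.13, 17.14, 16.47, 16.45],
    [16.28, 16.10, 16.11, 16.08, 16.10, 15.38, 15.39],
    [16.87, 16.46, 16.44, 16.43, 16.44, 15.97, 15.98],
    [22.61, 22.47, 22.46, 22.43, 22.44, 21.64, 21.63],
    [23.05, 22.81, 22.80, 22.79, 22.79, 22.44, 22.43],
    [17.53, 17.23, 17.24, 17.21, 17.22, 16.75, 16.74],
    [12.49, 12.31, 12.30, 12.29, 12.29, 11.83, 11.82],
    [7.52, 7.23, 7.21, 7.22, 7.24, 7.03, 7.02],
]


@dataclass
class ArrivalSchedule:
    """7x24 table of hourly arrival rates, ``rates[day][hour]``, day 0 = Monday."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (7, 24):
            raise ValidationError(
                f"arrival schedule must be 7x24 (day x hour), got {self.rates.shape}"
            )
        if np.any(self.rates < 0) or not np.all(np.isfinite(self.rates)):
            raise ValidationError("arrival rates must be finite and >= 0")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ArrivalSchedule) and np.array_equal(
            self.rates, other.rates
        )

    def weekly_mean_total(self, scale: float = 1.0) -> float:
        """Expected arrivals per simulated week (sum of all 168 hourly rates)."""
        return float(scale * self.rates.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rates.T, columns=list(DAY_NAMES)).rename_axis("hour")

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ArrivalSchedule":
        df = pd.read_csv(path)
        missing = [d for d in DAY_NAMES if d not in df.columns]
        if missing:
            raise SchemaError(f"arrival CSV missing day columns: {missing}")
        if len(df) != 24:
            raise SchemaError(f"arrival CSV must have 24 hour rows, got {len(df)}")
        return cls(df[list(DAY_NAMES)].to_numpy(dtype=float).T)


@dataclass(frozen=True)
class TriageConfig:
    """Triage mix over levels {3, 4} and per-level clinical wait targets (min)."""

    p_level3: float = 0.25
    target_wait: dict[int, float] = field(
        default_factory=lambda: {3: 30.0, 4: 120.0}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_level3 <= 1.0:
            raise ValidationError("p_level3 must lie in [0, 1]")
        if set(self.target_wait) != {3, 4}:
            raise ValidationError("target_wait must be keyed by levels 3 and 4")
        if any(v <= 0 for v in self.target_wait.values()):
            raise ValidationError("clinical wait targets must be > 0")

    @property
    def level_probs(self) -> dict[int, float]:
        return {3: self.p_level3, 4: 1.0 - self.p_level3}


@dataclass(frozen=True)
class ConsultationTimeConfig:
    """One consultation-duration distribution.

    ``mean`` is the mean of the *untruncated* base distribution (the rate
    parameter names the base exponential, not the post-truncation mean); the
    draw is then conditioned to lie in ``[lower, upper]``.  ``sigma`` is the
    lognormal shape and is only used when ``family == "trunclognorm"``, where
    the base log-mean is mu = ln(mean) - sigma^2/2 so the untruncated mean is
    preserved.
    """

    kind: str  # "initial" | "follow_up"
    family: str = "truncexp"  # "truncexp" | "trunclognorm"
    mean: float = 9.0
    lower: float = 5.0
    upper: float = 15.0
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ("initial", "follow_up"):
            raise ValidationError(f"unknown consultation kind {self.kind!r}")
        if self.family not in ("truncexp", "trunclognorm"):
            raise ValidationError(f"unknown duration family {self.family!r}")
        if not 0 < self.lower < self.upper:
            raise ValidationError("need 0 < lower < upper truncation bounds")
        if self.mean <= 0:
            raise ValidationError("mean must be > 0")
        if self.family == "trunclognorm" and self.sigma <= 0:
            raise ValidationError("sigma must be > 0 for the lognormal family")


@dataclass(frozen=True)
class ExamModality:
    """One diagnostic modality: requirement probability (conditional on the
    exam gate), processing time tau (min), report delay delta (min), and
    device capacity."""

    prob: float
    processing_time: float
    report_delay: float
    capacity: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValidationError("modality requirement probability must be in [0,1]")
        if self.processing_time <= 0:
            raise ValidationError("processing time must be > 0")
        if self.report_delay < 0:
            raise ValidationError("report delay must be >= 0")
        if int(self.capacity) != self.capacity or self.capacity < 1:
            raise ValidationError("device capacity must be an integer >= 1")


@dataclass(frozen=True)
class ExamConfig:
    """Examination subsystem: a global gate p_exam (probability an initial
    patient needs at least one exam) and four modalities with independent
    requirement probabilities conditional on passing the gate."""

    p_exam: float = 0.6
    modalities: dict[str, ExamModality] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_exam <= 1.0:
            raise ValidationError("p_exam must lie in [0, 1]")
        if set(self.modalities) != set(MODALITIES):
            raise ValidationError(f"exam config must define exactly {MODALITIES}")
        if self.p_exam > 0 and all(m.prob == 0 for m in self.modalities.values()):
            raise ValidationError(
                "p_exam > 0 with all modality probabilities 0: the "
                "at-least-one-exam requirement cannot be satisfied"
            )

    def __getattr__(self, name: str):
        # convenience: cfg.ct, cfg.xray, ...
        mods = object.__getattribute__(self, "modalities")
        if name in mods:
            return mods[name]
        raise AttributeError(name)


@dataclass(frozen=True)
class Shift:
    """Daily shift with clock-time boundaries in minutes after midnight.

    A shift may wrap past midnight (start > end, e.g. 22:00-07:00).
    """

    start: int
    end: int
    physicians: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < MINUTES_PER_DAY and 0 <= self.end <= MINUTES_PER_DAY):
            raise ValidationError("shift boundaries must lie within one day")
        if int(self.physicians) != self.physicians or self.physicians < 0:
            raise ValidationError("physician counts must be integers >= 0")


@dataclass
class StaffingSchedule:
    """Ordered daily shifts defining the scheduled physician count R(t)."""

    shifts: tuple[Shift, ...]

    def __post_init__(self) -> None:
        self.shifts = tuple(self.shifts)
        cover = np.full(MINUTES_PER_DAY, -1, dtype=int)
        for s in self.shifts:
            if s.start < s.end:
                span = range(s.start, s.end)
            else:  # wraps midnight
                span = list(range(s.start, MINUTES_PER_DAY)) + list(range(0, s.end))
            for m in span:
                if cover[m] != -1:
                    raise ValidationError(f"overlapping shifts at minute {m} of the day")
                cover[m] = s.physicians
        if np.any(cover == -1):
            gap = int(np.argmax(cover == -1))
            raise ValidationError(f"staffing gap at minute {gap} of the day")
        self._per_minute = cover

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StaffingSchedule) and self.shifts == other.shifts

    def physicians_at(self, t: float) -> int:
        """Scheduled physician count R(t) at simulation time t (minutes)."""
        if t < 0:
            raise ValueError("time must be >= 0")
        return int(self._per_minute[int(t) % MINUTES_PER_DAY])

    def change_points(self) -> list[tuple[int, int]]:
        """(minute-of-day, new count) at every within-day count change."""
        cover = self._per_minute
        points = []
        for m in range(MINUTES_PER_DAY):
            if cover[m] != cover[m - 1]:  # m-1 wraps to 1439, the weekly cycle
                points.append((m, int(cover[m])))
        return points

    def scheduled_minutes(self, horizon: float) -> float:
        """Total scheduled physician-minutes over [0, horizon)."""
        full_days, rem = divmod(int(round(horizon)), MINUTES_PER_DAY)
        total = full_days * float(self._per_minute.sum())
        total += float(self._per_minute[:rem].sum())
        return total

    def counts_tuple(self) -> tuple[int, ...]:
        return tuple(s.physicians for s in self.shifts)


@dataclass(frozen=True)
class PolicySpec:
    """Scheduling policy selector: "IFP" | "ALT" | "SBP" (SBP needs k1, k2)."""

    name: str = "IFP"
    k1: float | None = None
    k2: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("IFP", "ALT", "SBP"):
            raise ValidationError(f"unknown policy {self.name!r}")
        if self.name == "SBP":
            if self.k1 is None or self.k2 is None:
                raise SchemaError("policy SBP requires slack tolerances k1 and k2")
            if self.k1 < 0 or self.k2 < 0:
                raise ValidationError("slack tolerances k1, k2 must be >= 0")


@dataclass
class ScenarioConfig:
    """Complete immutable parameterization of one simulated ED world."""

    arrivals: ArrivalSchedule
    triage: TriageConfig
    consult_initial: ConsultationTimeConfig
    consult_followup: ConsultationTimeConfig
    exams: ExamConfig
    staffing: StaffingSchedule
    policy: PolicySpec = PolicySpec("IFP")
    horizon: float = float(MINUTES_PER_WEEK)
    n_reps: int = 100
    base_seed: int = 12345
    arrival_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.horizon <= 0 or self.horizon % MINUTES_PER_DAY != 0:
            raise ValidationError("horizon must be a positive multiple of 1440 min")
        if self.n_reps < 1:
            raise ValidationError("replication count must be >= 1")
        if self.arrival_scale < 0:
            raise ValidationError("arrival scale factor must be >= 0")
        if self.consult_initial.kind != "initial":
            raise ValidationError("consult_initial must have kind 'initial'")
        if self.consult_followup.kind != "follow_up":
            raise ValidationError("consult_followup must have kind 'follow_up'")

    # -- derived / convenience -------------------------------------------
    def scenario_hash(self) -> str:
        """Stable short hash of the full parameterization (for manifests)."""
        digest = hashlib.sha256(
            json.dumps(_to_dict(self), sort_keys=True).encode()
        ).hexdigest()
        return digest[:12]

    def with_policy(self, policy: PolicySpec) -> "ScenarioConfig":
        return replace(self, policy=policy)

    def with_arrival_scale(self, scale: float) -> "ScenarioConfig":
        return replace(self, arrival_scale=scale)

    def with_staffing_counts(self, morning: int, afternoon: int, night: int) -> "ScenarioConfig":
        """Keep the shift boundaries, swap the three physician counts."""
        if len(self.staffing.shifts) != 3:
            raise ValidationError("with_staffing_counts expects a three-shift roster")
        m, a, n = self.staffing.shifts
        return replace(
            self,
            staffing=StaffingSchedule(
                (
                    Shift(m.start, m.end, morning),
                    Shift(a.start, a.end, afternoon),
                    Shift(n.start, n.end, night),
                )
            ),
        )

    def with_consult_family(self, family: str, sigma: float = 0.3) -> "ScenarioConfig":
        """Swap both consultation distributions to ``family`` (same means/bounds)."""
        return replace(
            self,
            consult_initial=replace(self.consult_initial, family=family, sigma=sigma),
            consult_followup=replace(self.consult_followup, family=family, sigma=sigma),
        )


def default_baseline() -> ScenarioConfig:
    """The embedded baseline scenario of the case-study ED.

    Weekly-cyclic hourly arrival rates; 25% Level III / 75% Level IV with
    30/120-minute wait targets; truncated-exponential consultations with
    untruncated means 9 min on [5, 15] (initial) and 15 min on [5, 25]
    (follow-up); a 60% exam gate with modality probabilities 0.92/0.22/0.29/0.55
    (laboratory/B-ultrasound/X-ray/CT), processing times 1.19/6.58/3.99/2.45 min
    and report delays 20/0/30/30 min on one device each; shifts 07-15 and 15-22
    with 5 physicians, 22-07 with 3; a one-week horizon and 100 replications.
    """
    return ScenarioConfig(
        arrivals=ArrivalSchedule(np.array(_BASELINE_RATES_HOUR_BY_DAY).T),
        triage=TriageConfig(p_level3=0.25, target_wait={3: 30.0, 4: 120.0}),
        consult_initial=ConsultationTimeConfig("initial", "truncexp", 9.0, 5.0, 15.0),
        consult_followup=ConsultationTimeConfig("follow_up", "truncexp", 15.0, 5.0, 25.0),
        exams=ExamConfig(
            p_exam=0.6,
            modalities={
                "laboratory": ExamModality(0.92, 1.19, 20.0, 1),
                "ultrasound": ExamModality(0.22, 6.58, 0.0, 1),
                "xray": ExamModality(0.29, 3.99, 30.0, 1),
                "ct": ExamModality(0.55, 2.45, 30.0, 1),
            },
        ),
        staffing=StaffingSchedule(
            (
                Shift(7 * 60, 15 * 60, 5),
                Shift(15 * 60, 22 * 60, 5),
                Shift(22 * 60, 7 * 60, 3),
            )
        ),
        policy=PolicySpec("SBP", k1=13.1, k2=2.1),
        horizon=float(MINUTES_PER_WEEK),
        n_reps=100,
        base_seed=12345,
        arrival_scale=1.0,
    )


# ---------------------------------------------------------------------------
# Serialization (YAML schema)

def _to_dict(cfg: ScenarioConfig) -> dict:
    return {
        "arrivals": {"rates": cfg.arrivals.rates.tolist()},
        "triage": {
            "p_level3": cfg.triage.p_level3,
            "target_wait": {str(k): v for k, v in cfg.triage.target_wait.items()},
        },
        "consultations": {
            kind: {
                "family": c.family,
                "mean": c.mean,
                "bounds": [c.lower, c.upper],
                "sigma": c.sigma,
            }
            for kind, c in (
                ("initial", cfg.consult_initial),
                ("follow_up", cfg.consult_followup),
            )
        },
        "exams": {
            "p_exam": cfg.exams.p_exam,
            "modalities": {
                name: {
                    "prob": m.prob,
                    "processing_time": m.processing_time,
                    "report_delay": m.report_delay,
                    "capacity": m.capacity,
                }
                for name, m in cfg.exams.modalities.items()
            },
        },
        "staffing": [
            {"start": s.start, "end": s.end, "physicians": s.physicians}
            for s in cfg.staffing.shifts
        ],
        "policy": {"name": cfg.policy.name, "k1": cfg.policy.k1, "k2": cfg.policy.k2},
        "run": {
            "horizon": cfg.horizon,
            "n_reps": cfg.n_reps,
            "base_seed": cfg.base_seed,
            "arrival_scale": cfg.arrival_scale,
        },
    }


def _require(mapping: dict, key: str, where: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise SchemaError(f"missing field {key!r} in {where}")
    return mapping[key]


def _from_dict(doc: dict) -> ScenarioConfig:
    try:
        arr = ArrivalSchedule(np.asarray(_require(_require(doc, "arrivals", "scenario"), "rates", "arrivals"), dtype=float))
        tr_doc = _require(doc, "triage", "scenario")
        tw = {int(k): float(v) for k, v in _require(tr_doc, "target_wait", "triage").items()}
        triage = TriageConfig(float(_require(tr_doc, "p_level3", "triage")), tw)
        cons = _require(doc, "consultations", "scenario")
        consults = {}
        for kind in ("initial", "follow_up"):
            c = _require(cons, kind, "consultations")
            lo, hi = _require(c, "bounds", f"consultations.{kind}")
            consults[kind] = ConsultationTimeConfig(
                kind,
                _require(c, "family", f"consultations.{kind}"),
                float(_require(c, "mean", f"consultations.{kind}")),
                float(lo),
                float(hi),
                float(c.get("sigma", 0.3)),
            )
        ex_doc = _require(doc, "exams", "scenario")
        modalities = {}
        mods_doc = _require(ex_doc, "modalities", "exams")
        for name in MODALITIES:
            m = _require(mods_doc, name, "exams.modalities")
            modalities[name] = ExamModality(
                float(_require(m, "prob", name)),
                float(_require(m, "processing_time", name)),
                float(_require(m, "report_delay", name)),
                int(m.get("capacity", 1)),
            )
        exams = ExamConfig(float(_require(ex_doc, "p_exam", "exams")), modalities)
        staffing = StaffingSchedule(
            tuple(
                Shift(int(_require(s, "start", "staffing")), int(_require(s, "end", "staffing")), int(_require(s, "physicians", "staffing")))
                for s in _require(doc, "staffing", "scenario")
            )
        )
        pol_doc = _require(doc, "policy", "scenario")
        name = _require(pol_doc, "name", "policy")
        k1, k2 = pol_doc.get("k1"), pol_doc.get("k2")
        policy = PolicySpec(name, None if k1 is None else float(k1), None if k2 is None else float(k2))
        run = _require(doc, "run", "scenario")
        return ScenarioConfig(
            arrivals=arr,
            triage=triage,
            consult_initial=consults["initial"],
            consult_followup=consults["follow_up"],
            exams=exams,
            staffing=staffing,
            policy=policy,
            horizon=float(_require(run, "horizon", "run")),
            n_reps=int(_require(run, "n_reps", "run")),
            base_seed=int(_require(run, "base_seed", "run")),
            arrival_scale=float(run.get("arrival_scale", 1.0)),
        )
    except (TypeError, KeyError) as exc:  # malformed structure
        raise SchemaError(f"malformed scenario document: {exc}") from exc


def save_scenario(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_scenario(path: str | Path) -> ScenarioConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise SchemaError("scenario file is not a mapping")
    return _from_dict(doc)
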