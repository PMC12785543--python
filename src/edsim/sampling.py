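"""Consultation-duration and examination-requirement sampling.

Consultation durations come from a base family (exponential, or lognormal
with the log-mean chosen to preserve the stated untruncated mean) hard-
truncated to configured bounds: the exponential uses the exact inverse CDF of
the truncated law, the lognormal uses rejection.  Examination requirements
are a global gate (does the patient need any exam at all?) followed by
independent Bernoulli indicators per modality, resampled until at least one
modality is required; a patient's exams are then ordered by report delay
descending so the slowest-reporting results are under way first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import MODALITIES, ConsultationTimeConfig, ExamConfig

__all__ = [
    "ExamRequirement",
    "truncexp_mean",
    "sample_consult_duration",
    "sample_consult_durations",
    "sample_exam_requirements",
    "sample_exam_requirements_batch",
    "exam_order",
]

_MIN_TRUNCATION_MASS = 1e-12


class ConfigurationError(ValueError):
    """Sampling parameters admit (almost) no valid draws."""


def truncexp_mean(mean: float, lower: float, upper: float) -> float:
    """Closed-form mean of an exponential(mean) conditioned to [lower, upper].

    E[X | a <= X <= b] = a + m - (b-a) e^{-(b-a)/m} / (1 - e^{-(b-a)/m}).
    """
    w = (upper - lower) / mean
    return lower + mean - (upper - lower) * np.exp(-w) / (1.0 - np.exp(-w))


def _truncexp_draws(cfg: ConsultationTimeConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    a, b, m = cfg.lower, cfg.upper, cfg.mean
    mass = np.exp(-a / m) - np.exp(-b / m)
    if mass < _MIN_TRUNCATION_MASS:
        raise ConfigurationError(
            f"truncation interval [{a}, {b}] carries negligible mass "
            f"({mass:.3g}) under exponential mean {m}"
        )
    u = rng.random(n)
    # inverse CDF of the truncated exponential, shifted form
    x = a - m * np.log1p(-u * (1.0 - np.exp(-(b - a) / m)))
    return np.clip(x, np.nextafter(a, b), np.nextafter(b, a))


def _trunclognorm_draws(cfg: ConsultationTimeConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    a, b = cfg.lower, cfg.upper
    mu = np.log(cfg.mean) - 0.5 * cfg.sigma**2
    out = np.empty(n)
    need = np.arange(n)
    attempts = 0
    while need.size:
        draws = rng.lognormal(mu, cfg.sigma, need.size)
        ok = (draws > a) & (draws < b)
        out[need[ok]] = draws[ok]
        need = need[~ok]
        attempts += 1
        if attempts > 10_000:
            raise ConfigurationError(
                f"truncation interval [{a}, {b}] carries negligible lognormal mass"
            )
    return out


def sample_consult_durations(
    cfg: ConsultationTimeConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw ``n`` consultation durations (minutes), strictly inside the bounds."""
    if cfg.family == "truncexp":
        return _truncexp_draws(cfg, rng, n)
    return _trunclognorm_draws(cfg, rng, n)


def sample_consult_duration(cfg: ConsultationTimeConfig, rng: np.random.Generator) -> float:
    """Draw one consultation duration (minutes)."""
    return float(sample_consult_durations(cfg, rng, 1)[0])


@dataclass
class ExamRequirement:
    """Indicator vector over the modalities plus the derived exam order."""

    flags: dict[str, bool]
    order: tuple[str, ...] = field(default_factory=tuple)

    @property
    def any(self) -> bool:
        return any(self.flags.values())

    @property
    def required(self) -> tuple[str, ...]:
        return tuple(m for m in MODALITIES if self.flags.get(m, False))


def exam_order(req: ExamRequirement, cfg: ExamConfig) -> tuple[str, ...]:
    """Order a patient's required exams by report delay descending.

    Ties break by processing time descending, then by canonical modality
    order, so the ordering is a deterministic total order.
    """
    required = req.required
    if not required:
        raise ValueError("exam_order requires a nonempty requirement")
    idx = {m: i for i, m in enumerate(MODALITIES)}
    return tuple(
        sorted(
            required,
            key=lambda m: (
                -cfg.modalities[m].report_delay,
                -cfg.modalities[m].processing_time,
                idx[m],
            ),
        )
    )


def sample_exam_requirements(cfg: ExamConfig, rng: np.random.Generator) -> ExamRequirement:
    """Draw one patient's exam requirement.

    With probability 1 - p_exam the requirement is empty; otherwise each
    modality is an independent Bernoulli(p_j) and the whole vector is
    resampled until at least one modality is required.
    """
    if rng.random() >= cfg.p_exam:
        return ExamRequirement({m: False for m in MODALITIES})
    probs = np.array([cfg.modalities[m].prob for m in MODALITIES])
    while True:
        draws = rng.random(len(MODALITIES)) < probs
        if draws.any():
            break
    flags = {m: bool(d) for m, d in zip(MODALITIES, draws)}
    req = ExamRequirement(flags)
    req.order = exam_order(req, cfg)
    return req


def sample_exam_requirements_batch(
    cfg: ExamConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Vectorized requirements for ``n`` patients: (n, 4) boolean array in
    canonical modality order; all-False rows are patients needing no exam."""
    gate = rng.random(n) < cfg.p_exam
    flags = np.zeros((n, len(MODALITIES)), dtype=bool)
    probs = np.array([cfg.modalities[m].prob for m in MODALITIES])
    pending = np.flatnonzero(gate)
    attempts = 0
    while pending.size:
        draws = rng.random((pending.size, len(MODALITIES))) < probs
        ok = draws.any(axis=1)
        flags[pending[ok]] = draws[ok]
        pending = pending[~ok]
        attempts += 1
        if attempts > 10_000:
            raise ConfigurationError(
                "p_exam > 0 with all modality probabilities ~0: "
                "at-least-one-exam resampling cannot terminate"
            )
    return flags
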