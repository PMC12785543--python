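"""Reusable study procedures: slack-threshold optimization, policy comparison
with paired statistics, and sensitivity analyses.

All procedures run every compared configuration on the same replication seed
set (``base_seed + r``), i.e. under common random numbers, so paired
differences isolate the policy effect from arrival/service noise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .config import PolicySpec, ScenarioConfig
from .engine import run_replication
from .metrics import ReplicationMetrics, aggregate, metrics_frame, summarize

__all__ = [
    "GridSearchResult",
    "ComparisonReport",
    "run_policy_metrics",
    "grid_search",
    "two_stage_optimize",
    "compare_policies",
    "arrival_sensitivity",
    "staffing_sensitivity",
    "distribution_robustness",
    "BONFERRONI_ALPHA",
]

logger = logging.getLogger(__name__)

#: family-wise 0.05 split over the three pairwise comparisons
BONFERRONI_ALPHA = 0.05 / 3

#: KPI used as the optimization objective and for paired comparisons:
#: the per-patient cumulative waiting time averaged over all patients.
OBJECTIVE = "w_overall"

#: Arrival-rate scale sweep: +/-15% of baseline in 3% increments.
ARRIVAL_SCALES = tuple(round(0.85 + 0.03 * i, 2) for i in range(11))


def run_policy_metrics(
    config: ScenarioConfig,
    policy: PolicySpec | None = None,
    n_reps: int | None = None,
    base_seed: int | None = None,
) -> list[ReplicationMetrics]:
    """Run replications of one policy and summarize each."""
    cfg = config if policy is None else config.with_policy(policy)
    n_reps = cfg.n_reps if n_reps is None else n_reps
    base_seed = cfg.base_seed if base_seed is None else base_seed
    out = []
    for r in range(n_reps):
        res = run_replication(cfg, seed=base_seed + r)
        out.append(summarize(res, cfg))
    return out


@dataclass
class GridSearchResult:
    """Ranked grid cells and the service-level-constrained argmin."""

    table: pd.DataFrame  # k1, k2, mean_wait, sd, ci_lo, ci_hi, sl3, sl4, feasible
    best: tuple[float, float]
    feasible: bool  # False -> no cell met the SL constraints (warning path)

    @property
    def best_row(self) -> pd.Series:
        mask = (self.table["k1"] == self.best[0]) & (self.table["k2"] == self.best[1])
        return self.table[mask].iloc[0]


def grid_search(
    config: ScenarioConfig,
    k1_values,
    k2_values,
    n_reps: int = 50,
    sl_min3: float = 0.95,
    sl_min4: float = 0.95,
    base_seed: int | None = None,
) -> GridSearchResult:
    """Evaluate SBP over a (k1, k2) grid under common random numbers.

    Every cell runs the same ``n_reps`` seeds; cells are ranked by mean
    overall waiting time and filtered by the mean service-level constraints.
    If no cell is feasible the unconstrained ranking is returned with a
    feasibility warning.
    """
    k1_values = list(k1_values)
    k2_values = list(k2_values)
    if not k1_values or not k2_values:
        raise ValueError("grid search requires nonempty k1 and k2 grids")
    if n_reps < 2:
        raise ValueError("grid search requires n_reps >= 2")
    base_seed = config.base_seed if base_seed is None else base_seed
    rows = []
    for k1, k2 in itertools.product(k1_values, k2_values):
        mets = run_policy_metrics(
            config, PolicySpec("SBP", k1, k2), n_reps=n_reps, base_seed=base_seed
        )
        agg = aggregate(mets)
        row = {
            "k1": k1,
            "k2": k2,
            "mean_wait": agg.loc[OBJECTIVE, "mean"],
            "sd": agg.loc[OBJECTIVE, "sd"],
            "ci_lo": agg.loc[OBJECTIVE, "ci_lo"],
            "ci_hi": agg.loc[OBJECTIVE, "ci_hi"],
            "sl3": agg.loc["sl3", "mean"],
            "sl4": agg.loc["sl4", "mean"],
        }
        row["feasible"] = row["sl3"] >= sl_min3 and row["sl4"] >= sl_min4
        rows.append(row)
    # ties (possible when thresholds never bind) break by (k1, k2) ascending
    table = (
        pd.DataFrame(rows)
        .sort_values(["mean_wait", "k1", "k2"], kind="stable")
        .reset_index(drop=True)
    )
    feas = table[table["feasible"]]
    if len(feas):
        best = feas.iloc[0]
        feasible = True
    else:
        logger.warning(
            "grid search: no (k1, k2) cell met the service-level constraints "
            "(SL3 >= %.3f, SL4 >= %.3f); returning the unconstrained optimum",
            sl_min3,
            sl_min4,
        )
        best = table.iloc[0]
        feasible = False
    return GridSearchResult(table, (float(best["k1"]), float(best["k2"])), feasible)


def two_stage_optimize(
    config: ScenarioConfig,
    coarse_range: tuple[float, float] = (0.0, 40.0),
    coarse_step: float = 1.0,
    coarse_reps: int = 50,
    fine_halfwidth: float = 1.0,
    fine_step: float = 0.1,
    fine_reps: int = 100,
    sl_min3: float = 0.95,
    sl_min4: float = 0.95,
    base_seed: int | None = None,
) -> tuple[tuple[float, float], GridSearchResult, GridSearchResult]:
    """Coarse-then-fine grid search for the SBP slack tolerances.

    Stage 1 scans ``coarse_range`` squared at ``coarse_step``; stage 2 scans
    the +/- ``fine_halfwidth`` neighborhood of the stage-1 argmin at
    ``fine_step`` with more replications.  Returns (best pair, coarse result,
    fine result).
    """
    lo, hi = coarse_range
    grid1 = _arange_inclusive(lo, hi, coarse_step)
    coarse = grid_search(config, grid1, grid1, coarse_reps, sl_min3, sl_min4, base_seed)
    c1, c2 = coarse.best
    grid_k1 = _arange_inclusive(max(lo, c1 - fine_halfwidth), c1 + fine_halfwidth, fine_step)
    grid_k2 = _arange_inclusive(max(lo, c2 - fine_halfwidth), c2 + fine_halfwidth, fine_step)
    fine = grid_search(config, grid_k1, grid_k2, fine_reps, sl_min3, sl_min4, base_seed)
    return fine.best, coarse, fine


def _arange_inclusive(lo: float, hi: float, step: float) -> list[float]:
    n = int(round((hi - lo) / step))
    return [round(lo + i * step, 10) for i in range(n + 1)]


@dataclass
class ComparisonReport:
    """Per-policy aggregates plus pairwise paired statistics."""

    policies: list[str]
    summaries: dict[str, pd.DataFrame]
    per_rep: dict[str, pd.DataFrame]
    pairwise: pd.DataFrame  # pair, mean_diff, t, p, significant, cohens_d

    def mean(self, policy: str, kpi: str = OBJECTIVE) -> float:
        return float(self.summaries[policy].loc[kpi, "mean"])


def compare_policies(
    config: ScenarioConfig,
    policies: list[PolicySpec],
    n_reps: int | None = None,
    base_seed: int | None = None,
    kpi: str = OBJECTIVE,
) -> ComparisonReport:
    """Run each policy on identical random streams and compare pairwise.

    For each ordered pair the paired differences of the per-replication KPI
    feed a two-sided paired t-test; significance uses the Bonferroni-adjusted
    level 0.05/3 and the paired effect size is Cohen's d = mean(diff)/sd(diff)
    (equivalently t/sqrt(n)).
    """
    if len(policies) < 2:
        raise ValueError("compare_policies requires at least two policies")
    names = [p.name for p in policies]
    if len(set(names)) != len(names):
        names = [f"{p.name}#{i}" for i, p in enumerate(policies)]
    per_rep: dict[str, pd.DataFrame] = {}
    summaries: dict[str, pd.DataFrame] = {}
    for name, spec in zip(names, policies):
        mets = run_policy_metrics(config, spec, n_reps=n_reps, base_seed=base_seed)
        per_rep[name] = metrics_frame(mets)
        summaries[name] = aggregate(mets)
    rows = []
    for a, b in itertools.combinations(names, 2):
        diff = per_rep[a][kpi].to_numpy() - per_rep[b][kpi].to_numpy()
        n = diff.size
        sd = diff.std(ddof=1)
        if sd == 0:
            t_stat, p_val, d = math.nan, math.nan, 0.0 if diff.mean() == 0 else math.nan
        else:
            t_stat, p_val = stats.ttest_rel(per_rep[a][kpi], per_rep[b][kpi])
            d = float(diff.mean() / sd)
        rows.append(
            {
                "pair": f"{a} vs. {b}",
                "mean_diff": float(diff.mean()),
                "t": float(t_stat) if not math.isnan(t_stat) else math.nan,
                "p": float(p_val) if not math.isnan(p_val) else math.nan,
                "significant": bool(p_val < BONFERRONI_ALPHA) if not math.isnan(p_val) else False,
                "cohens_d": d,
                "n": n,
            }
        )
    return ComparisonReport(names, summaries, per_rep, pd.DataFrame(rows))


def default_policy_set(config: ScenarioConfig) -> list[PolicySpec]:
    """IFP, ALT, and the scenario's SBP spec (must carry k1, k2)."""
    if config.policy.name != "SBP":
        raise ValueError("scenario policy must be SBP (with k1, k2) to build the trio")
    return [PolicySpec("IFP"), PolicySpec("ALT"), config.policy]


def arrival_sensitivity(
    config: ScenarioConfig,
    policies: list[PolicySpec] | None = None,
    scales=None,
    n_reps: int | None = None,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Re-run the policy comparison under scaled arrival rates.

    Default scales sweep +/-15% of baseline in 3% steps (11 scenarios).
    Returns a tidy frame (scale, policy, mean_wait, sd, ci_lo, ci_hi).
    """
    if policies is None:
        policies = default_policy_set(config)
    if scales is None:
        scales = ARRIVAL_SCALES
    rows = []
    for scale in scales:
        rep = compare_policies(
            config.with_arrival_scale(scale), policies, n_reps, base_seed
        )
        for name in rep.policies:
            s = rep.summaries[name].loc[OBJECTIVE]
            rows.append(
                {
                    "scale": scale,
                    "policy": name,
                    "mean_wait": s["mean"],
                    "sd": s["sd"],
                    "ci_lo": s["ci_lo"],
                    "ci_hi": s["ci_hi"],
                }
            )
    return pd.DataFrame(rows)


#: Shift-count triples (morning, afternoon, night) for the staffing sweep.
STAFFING_SCENARIOS = {
    "S0": (5, 5, 3),
    "S1": (5, 5, 4),
    "S2": (5, 5, 5),
    "S3": (5, 6, 5),
    "S4": (5, 7, 5),
    "S5": (6, 7, 5),
    "S6": (7, 7, 5),
}


def staffing_sensitivity(
    config: ScenarioConfig,
    policies: list[PolicySpec] | None = None,
    scenarios: dict[str, tuple[int, int, int]] | None = None,
    n_reps: int | None = None,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Re-run the policy comparison under the S0-S6 staffing ladder."""
    if policies is None:
        policies = default_policy_set(config)
    if scenarios is None:
        scenarios = STAFFING_SCENARIOS
    rows = []
    for label, (m, a, n) in scenarios.items():
        rep = compare_policies(
            config.with_staffing_counts(m, a, n), policies, n_reps, base_seed
        )
        for name in rep.policies:
            s = rep.summaries[name].loc[OBJECTIVE]
            rows.append(
                {
                    "scenario": label,
                    "staffing": (m, a, n),
                    "policy": name,
                    "mean_wait": s["mean"],
                    "sd": s["sd"],
                    "ci_lo": s["ci_lo"],
                    "ci_hi": s["ci_hi"],
                }
            )
    return pd.DataFrame(rows)


def distribution_robustness(
    config: ScenarioConfig,
    policies: list[PolicySpec] | None = None,
    sigma: float = 0.3,
    n_reps: int | None = None,
    base_seed: int | None = None,
) -> ComparisonReport:
    """Swap both consultation families to truncated lognormal and re-compare.

    The lognormal shape is ``sigma`` with log-mean ln(mean) - sigma^2/2, so
    the untruncated means (9 and 15 min) are preserved; truncation bounds are
    unchanged.
    """
    if policies is None:
        policies = default_policy_set(config)
    return compare_policies(
        config.with_consult_family("trunclognorm", sigma), policies, n_reps, base_seed
    )
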