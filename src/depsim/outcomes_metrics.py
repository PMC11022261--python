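"""Primary outcome and plausibility statistics.

The primary outcome is the disease burden: the proportion of lived
person-months spent in depression, taken over the whole cohort including
never-ill lives.  Burden reduction compares a scenario with the
no-healthcare null run-by-run (the runs are paired through shared per-run
seeds when common random numbers are enabled) and is reported on the
percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population_mc import CohortSummary, ReplicateSet, confidence_interval

__all__ = ["BurdenResult", "PlausibilityStats", "disease_burden",
           "burden_reduction", "plausibility_report", "plausibility_frame"]


@dataclass
class BurdenResult:
    burden: float           # scenario burden (fraction of person-months)
    null_burden: float
    reduction_pct: float    # mean per-run (B0 - B1) / B0, percent scale
    ci_low: float
    ci_high: float
    n_runs: int


@dataclass
class PlausibilityStats:
    """Population-level model predictions checked against the literature.

    Per-case statistics use affected individuals as the denominator; the
    chronic burden share uses diseased months.  Fields are ``nan`` when the
    denominator is empty.
    """

    n_lives: int
    life_expectancy_years: dict          # {"female": .., "male": .., "all": ..}
    lifetime_incidence: float            # fraction of lives ever depressed
    treated_at_least_once: float         # fraction of depressed
    mean_episodes: float                 # per affected individual
    sd_episodes: float
    recurrence_fraction: float           # fraction of affected with >= 2 episodes
    mean_episode_duration: float         # months, all completed episodes
    sd_episode_duration: float
    mean_duration_non_chronic: float
    sd_duration_non_chronic: float
    mean_duration_chronic: float
    sd_duration_chronic: float
    chronic_fraction: float              # fraction of affected
    fraction_long_episode: float         # affected with an episode > 24 months
    fraction_three_plus_episodes: float
    chronic_burden_share: float          # fraction of diseased months in chronic lives


def disease_burden(summary: CohortSummary, per_affected: bool = False) -> float:
    """Proportion of person-months spent in depression.

    By default the denominator is every lived month of the whole cohort;
    ``per_affected=True`` restricts the denominator to months lived by
    individuals who were ever depressed.
    """
    if summary.total_months_alive == 0:
        raise ValueError("disease burden undefined for an empty cohort")
    if not per_affected:
        return summary.total_months_diseased / summary.total_months_alive
    if summary.total_months_alive_affected == 0:
        raise ValueError("per-affected burden undefined without affected lives")
    return summary.total_months_diseased / summary.total_months_alive_affected


def burden_reduction(scenario: ReplicateSet, null: ReplicateSet,
                     level: float = 0.95, ci_method: str = "mean") -> BurdenResult:
    """Relative burden reduction of a scenario versus the no-healthcare null.

    Per run ``i``: ``r_i = (B0_i - B1_i) / B0_i``; the point estimate is the
    mean of the ``r_i`` and the reported interval is, by default, the
    confidence interval of that Monte Carlo mean (mean +/- z * SD / sqrt(n)),
    so it narrows as replicates are added; ``ci_method="percentile"`` gives
    the replicate-spread interval instead.
    """
    if scenario.n_runs != null.n_runs:
        raise ValueError("scenario and null must have the same number of runs")
    b1 = np.asarray(scenario.burdens, dtype=float)
    b0 = np.asarray(null.burdens, dtype=float)
    if np.any(b0 == 0):
        raise ValueError("degenerate null: zero burden in at least one run")
    r = (b0 - b1) / b0
    if len(r) >= 2:
        lo, hi = confidence_interval(r, level, method=ci_method)
    else:
        lo = hi = float(r[0])
    return BurdenResult(
        burden=float(b1.mean()),
        null_burden=float(b0.mean()),
        reduction_pct=float(r.mean() * 100.0),
        ci_low=float(lo * 100.0),
        ci_high=float(hi * 100.0),
        n_runs=scenario.n_runs,
    )


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    if len(x) == 0:
        return float("nan"), float("nan")
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")


def plausibility_report(summary: CohortSummary) -> PlausibilityStats:
    """Compute the population-level plausibility statistics of one cohort."""
    if summary.n_lives == 0:
        raise ValueError("plausibility report undefined for an empty cohort")
    n_aff = summary.n_ever_depressed
    dist = summary.episode_count_distribution
    counts = np.arange(len(dist))
    if n_aff:
        mean_ep = float((dist * counts).sum() / n_aff)
        var_ep = float((dist * (counts - mean_ep) ** 2)[1:].sum() / max(n_aff - 1, 1))
        sd_ep = float(np.sqrt(var_ep))
    else:
        mean_ep = sd_ep = float("nan")
    dur_c = summary.episode_durations["chronic"]
    dur_nc = summary.episode_durations["non_chronic"]
    dur_all = np.concatenate([dur_c, dur_nc])
    m_all, s_all = _mean_sd(dur_all)
    m_nc, s_nc = _mean_sd(dur_nc)
    m_c, s_c = _mean_sd(dur_c)
    dm = summary.diseased_months_by_chronicity
    dm_total = dm["chronic"] + dm["non_chronic"]
    le = {}
    for i, name in enumerate(("female", "male")):
        nl = summary.n_lives_by_sex[i]
        le[name] = float(summary.total_months_alive_by_sex[i] / nl / 12.0) if nl else float("nan")
    le["all"] = summary.total_months_alive / summary.n_lives / 12.0

    def frac(x, denom):
        return x / denom if denom else float("nan")

    return PlausibilityStats(
        n_lives=summary.n_lives,
        life_expectancy_years=le,
        lifetime_incidence=n_aff / summary.n_lives,
        treated_at_least_once=frac(summary.n_ever_treated, n_aff),
        mean_episodes=mean_ep,
        sd_episodes=sd_ep,
        recurrence_fraction=frac(summary.n_with_recurrence, n_aff),
        mean_episode_duration=m_all,
        sd_episode_duration=s_all,
        mean_duration_non_chronic=m_nc,
        sd_duration_non_chronic=s_nc,
        mean_duration_chronic=m_c,
        sd_duration_chronic=s_c,
        chronic_fraction=frac(summary.chronic_counts["chronic"], n_aff),
        fraction_long_episode=frac(summary.n_with_long_episode, n_aff),
        fraction_three_plus_episodes=frac(summary.n_three_plus_episodes, n_aff),
        chronic_burden_share=frac(dm["chronic"], dm_total),
    )


def plausibility_frame(stats: PlausibilityStats) -> pd.DataFrame:
    """Plausibility statistics as a tidy one-row-per-statistic table."""
    rows = [
        ("life_expectancy_female_years", stats.life_expectancy_years["female"]),
        ("life_expectancy_male_years", stats.life_expectancy_years["male"]),
        ("lifetime_incidence", stats.lifetime_incidence),
        ("treated_at_least_once", stats.treated_at_least_once),
        ("mean_episodes_per_affected", stats.mean_episodes),
        ("sd_episodes_per_affected", stats.sd_episodes),
        ("recurrence_fraction", stats.recurrence_fraction),
        ("mean_episode_duration_months", stats.mean_episode_duration),
        ("sd_episode_duration_months", stats.sd_episode_duration),
        ("mean_duration_non_chronic", stats.mean_duration_non_chronic),
        ("sd_duration_non_chronic", stats.sd_duration_non_chronic),
        ("mean_duration_chronic", stats.mean_duration_chronic),
        ("sd_duration_chronic", stats.sd_duration_chronic),
        ("chronic_fraction", stats.chronic_fraction),
        ("fraction_long_episode", stats.fraction_long_episode),
        ("fraction_three_plus_episodes", stats.fraction_three_plus_episodes),
        ("chronic_burden_share", stats.chronic_burden_share),
        ("n_lives", stats.n_lives),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])
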