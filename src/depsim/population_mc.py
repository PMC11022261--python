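"""Monte Carlo replicates: seeding, aggregation, confidence intervals,
calibration of non-printed defaults.

Seeds are derived with numpy's splittable ``SeedSequence``: run *i* of a
replicate set uses ``SeedSequence(base_seed, spawn_key=(i,))``.  The
derivation is a pure function of ``(base_seed, i)``, so replicates are
independent, order-invariant, and two replicate sets started from the same
base seed share per-run streams (common random numbers for paired
scenario/null comparisons).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CohortArrays, simulate_cohort
from .params_config import ModelConfig, SimulationSettings, get_param, set_param, validate_config

__all__ = ["CohortSummary", "ReplicateSet", "run_cohort", "run_replicates",
           "merge_summaries", "confidence_interval", "calibrate",
           "CalibrationError"]


@dataclass
class CohortSummary:
    """Aggregate person-month and case tallies for one cohort.

    Episode durations are kept as raw arrays split by the life's chronicity
    class, so merged summaries can still compute exact means and SDs.
    Durations truncated by death count as episodes.
    """

    n_lives: int = 0
    n_lives_by_sex: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    total_months_alive: int = 0
    total_months_alive_by_sex: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    total_months_diseased: int = 0
    total_months_alive_affected: int = 0
    n_ever_depressed: int = 0
    n_ever_treated: int = 0
    n_with_recurrence: int = 0
    n_with_long_episode: int = 0        # >= 1 episode longer than 24 months
    n_three_plus_episodes: int = 0
    episode_count_distribution: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=np.int64))
    episode_durations: dict = field(default_factory=lambda: {
        "chronic": np.zeros(0, dtype=np.int32),
        "non_chronic": np.zeros(0, dtype=np.int32)})
    chronic_counts: dict = field(default_factory=lambda: {"chronic": 0, "non_chronic": 0})
    diseased_months_by_chronicity: dict = field(default_factory=lambda: {"chronic": 0, "non_chronic": 0})


def summarize_cohort(arrays: CohortArrays) -> CohortSummary:
    a = arrays
    n = len(a.months_alive)
    affected = a.n_episodes > 0
    chronic = affected & ((a.max_episode_duration > 24) | (a.n_episodes >= 3))
    non_chronic = affected & ~chronic
    counts = np.bincount(a.n_episodes.astype(np.int64), minlength=1)
    ep_chronic = chronic[a.episode_life_index] if len(a.episode_life_index) else np.zeros(0, bool)
    return CohortSummary(
        n_lives=n,
        n_lives_by_sex=np.bincount(a.sex, minlength=2).astype(np.int64),
        total_months_alive=int(a.months_alive.sum()),
        total_months_alive_by_sex=np.bincount(a.sex, weights=a.months_alive, minlength=2).astype(np.int64),
        total_months_diseased=int(a.months_diseased.sum()),
        total_months_alive_affected=int(a.months_alive[affected].sum()),
        n_ever_depressed=int(affected.sum()),
        n_ever_treated=int(a.ever_treated.sum()),
        n_with_recurrence=int((a.n_episodes >= 2).sum()),
        n_with_long_episode=int((a.max_episode_duration > 24).sum()),
        n_three_plus_episodes=int((a.n_episodes >= 3).sum()),
        episode_count_distribution=counts,
        episode_durations={
            "chronic": a.episode_durations[ep_chronic],
            "non_chronic": a.episode_durations[~ep_chronic] if len(ep_chronic) else a.episode_durations,
        },
        chronic_counts={"chronic": int(chronic.sum()), "non_chronic": int(non_chronic.sum())},
        diseased_months_by_chronicity={
            "chronic": int(a.months_diseased[chronic].sum()),
            "non_chronic": int(a.months_diseased[non_chronic].sum())},
    )


def merge_summaries(summaries: list[CohortSummary]) -> CohortSummary:
    """Concatenation of cohorts: all tallies add, duration arrays concatenate."""
    if not summaries:
        return CohortSummary()
    out = CohortSummary()
    max_len = max(len(s.episode_count_distribution) for s in summaries)
    dist = np.zeros(max_len, dtype=np.int64)
    for s in summaries:
        out.n_lives += s.n_lives
        out.n_lives_by_sex = out.n_lives_by_sex + s.n_lives_by_sex
        out.total_months_alive += s.total_months_alive
        out.total_months_alive_by_sex = out.total_months_alive_by_sex + s.total_months_alive_by_sex
        out.total_months_diseased += s.total_months_diseased
        out.total_months_alive_affected += s.total_months_alive_affected
        out.n_ever_depressed += s.n_ever_depressed
        out.n_ever_treated += s.n_ever_treated
        out.n_with_recurrence += s.n_with_recurrence
        out.n_with_long_episode += s.n_with_long_episode
        out.n_three_plus_episodes += s.n_three_plus_episodes
        dist[:len(s.episode_count_distribution)] += s.episode_count_distribution
        for k in ("chronic", "non_chronic"):
            out.chronic_counts[k] += s.chronic_counts[k]
            out.diseased_months_by_chronicity[k] += s.diseased_months_by_chronicity[k]
    out.episode_count_distribution = dist
    for k in ("chronic", "non_chronic"):
        out.episode_durations[k] = np.concatenate(
            [s.episode_durations[k] for s in summaries])
    return out


@dataclass
class ReplicateSet:
    """Per-run summaries plus the per-run disease-burden vector."""

    summaries: list
    burdens: np.ndarray
    base_seed: int
    n_runs: int

    def merged(self) -> CohortSummary:
        return merge_summaries(self.summaries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.summaries):
            rows.append({
                "run_id": i,
                "seed": f"{self.base_seed}:{i}",
                "burden": self.burdens[i],
                "lifetime_incidence": s.n_ever_depressed / s.n_lives if s.n_lives else np.nan,
                "n_lives": s.n_lives,
            })
        return pd.DataFrame(rows)


def run_seed(base_seed: int, run_index: int) -> np.random.SeedSequence:
    """Deterministic, splittable seed for one replicate."""
    return np.random.SeedSequence(base_seed, spawn_key=(run_index,))


def run_cohort(cfg: ModelConfig, n_lives: int, seed) -> CohortSummary:
    """Simulate ``n_lives`` independent lives from a seeded stream.

    ``seed`` may be an integer or a ``SeedSequence``.  The summary is
    bit-identically reproducible for a fixed (config, n, seed).
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    rng = np.random.default_rng(seed)
    return summarize_cohort(simulate_cohort(cfg, n_lives, rng))


def run_replicates(cfg: ModelConfig, settings: SimulationSettings | None = None,
                   progress: bool = False) -> ReplicateSet:
    """Run ``n_runs`` independently seeded cohorts of ``n_lives_per_run``.

    Per-run seeds depend only on ``(base_seed, run index)``, so results are
    identical whether runs execute serially or concurrently, and replicate
    sets sharing a base seed share per-run random streams.
    """
    st = settings or cfg.simulation
    summaries = []
    burdens = np.zeros(st.n_runs, dtype=float)
    for i in range(st.n_runs):
        s = run_cohort(cfg, st.n_lives_per_run, run_seed(st.base_seed, i))
        summaries.append(s)
        burdens[i] = (s.total_months_diseased / s.total_months_alive
                      if s.total_months_alive else np.nan)
    return ReplicateSet(summaries=summaries, burdens=burdens,
                        base_seed=st.base_seed, n_runs=st.n_runs)


def confidence_interval(values, level: float = 0.95,
                        method: str = "percentile") -> tuple[float, float]:
    """Interval over per-run outcomes.

    ``percentile`` (default) takes the (1 +/- level)/2 linear-interpolation
    quantiles of the replicate distribution; ``normal`` uses mean +/- z * SD
    (also a spread interval); ``mean`` uses mean +/- z * SD / sqrt(n), the
    confidence interval of the Monte Carlo mean, which narrows ~1/sqrt(n_runs)
    and is what the reported scenario intervals use.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("confidence_interval requires at least 2 values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    if method == "percentile":
        lo, hi = np.quantile(v, [alpha, 1.0 - alpha])
    elif method in ("normal", "mean"):
        z = statistics.NormalDist().inv_cdf(1.0 - alpha)
        m, sd = v.mean(), v.std(ddof=1)
        if method == "mean":
            sd = sd / np.sqrt(v.size)
        lo, hi = m - z * sd, m + z * sd
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(lo), float(hi)


class CalibrationError(RuntimeError):
    """Raised when calibration does not reach its targets; carries the best
    configuration found in ``.best`` and its statistics in ``.achieved``."""

    def __init__(self, msg, best, achieved):
        super().__init__(msg)
        self.best = best
        self.achieved = achieved


def _stats_for(cfg: ModelConfig, target_names, n_lives: int, seed: int) -> dict:
    from .outcomes_metrics import plausibility_report

    summary = run_cohort(cfg, n_lives, np.random.SeedSequence(seed))
    rep = plausibility_report(summary)
    return {name: getattr(rep, name) for name in target_names}


def calibrate(cfg: ModelConfig, free_params: dict, targets: dict,
              n_lives: int = 50000, seed: int = 1234,
              max_iter: int = 40) -> ModelConfig:
    """Tune non-printed defaults until simulated statistics hit targets.

    Parameters
    ----------
    free_params : dict
        ``{dotted parameter path: (lower, upper)}`` search bounds, e.g.
        ``{"course.incidence_scale": (0.01, 1.0)}``.
    targets : dict
        ``{plausibility statistic name: (target value, tolerance)}``, e.g.
        ``{"lifetime_incidence": (0.114, 0.005)}``.
    n_lives, seed :
        Size and fixed seed of each objective evaluation; the fixed seed
        makes the objective deterministic, so coordinate search is stable.

    Returns the calibrated config (achieved statistics recorded under
    ``metadata["calibration"]``) or raises :class:`CalibrationError`.
    """
    if not free_params:
        return cfg.copy()
    names = list(targets)

    def loss(c: ModelConfig) -> tuple[float, dict]:
        stats = _stats_for(c, names, n_lives, seed)
        return sum(((stats[k] - targets[k][0]) / targets[k][1]) ** 2
                   for k in names), stats

    best = cfg.copy()
    best_loss, best_stats = loss(best)
    steps = {p: 0.25 * (hi - lo) for p, (lo, hi) in free_params.items()}
    for _ in range(max_iter):
        if all(abs(best_stats[k] - targets[k][0]) <= targets[k][1] for k in names):
            break
        improved = False
        for path, (lo, hi) in free_params.items():
            cur = get_param(best, path)
            for cand in (cur + steps[path], cur - steps[path]):
                cand = min(max(cand, lo), hi)
                if cand == cur:
                    continue
                trial = set_param(best, path, cand)
                l, stats = loss(trial)
                if l < best_loss:
                    best, best_loss, best_stats = trial, l, stats
                    improved = True
                    break
        if not improved:
            for path in steps:
                steps[path] *= 0.5
            if max(steps.values()) < 1e-6:
                break
    achieved = {k: best_stats[k] for k in names}
    if not all(abs(achieved[k] - targets[k][0]) <= targets[k][1] for k in names):
        raise CalibrationError(
            f"calibration did not reach targets {targets}; achieved {achieved}",
            best, achieved)
    best.metadata = dict(best.metadata)
    best.metadata["calibration"] = {
        "targets": {k: list(v) for k, v in targets.items()},
        "achieved": achieved,
        "free_params": {p: get_param(best, p) for p in free_params},
        "n_lives": n_lives,
        "seed": seed,
    }
    return best
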