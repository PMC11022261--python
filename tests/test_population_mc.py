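import numpy as np
import pytest

import depsim as ds
from depsim.engine import simulate_cohort
from depsim.lifecourse import simulate_life
from depsim.population_mc import (CalibrationError, calibrate,
                                  confidence_interval, merge_summaries,
                                  run_cohort, run_replicates, run_seed,
                                  summarize_cohort)
from depsim.params_config import set_param

from conftest import make_reduced_config


class TestRunCohort:
    def test_empty_cohort(self, reduced_cfg):
        s = run_cohort(reduced_cfg, 0, 1)
        assert s.n_lives == 0 and s.total_months_alive == 0

    def test_zero_incidence(self):
        cfg = make_reduced_config(monthly_onset=0.0)
        s = run_cohort(cfg, 300, 7)
        assert s.n_ever_depressed == 0
        assert s.total_months_diseased == 0
        assert s.total_months_alive == 300 * 240

    def test_bit_identical_for_fixed_seed(self, reduced_cfg):
        a = run_cohort(reduced_cfg, 500, 99)
        b = run_cohort(reduced_cfg, 500, 99)
        assert a.total_months_diseased == b.total_months_diseased
        assert np.array_equal(a.episode_count_distribution,
                              b.episode_count_distribution)
        assert np.array_equal(a.episode_durations["chronic"],
                              b.episode_durations["chronic"])

    def test_invalid_config_rejected_before_simulation(self, reduced_cfg):
        bad = set_param(reduced_cfg, "services.treatment_reach", 2.0)
        with pytest.raises(ValueError, match="treatment_reach"):
            run_cohort(bad, 10, 1)


class TestReplicates:
    def test_single_run_wraps_run_cohort(self, reduced_cfg):
        reduced_cfg.simulation.n_runs = 1
        reps = run_replicates(reduced_cfg)
        direct = run_cohort(reduced_cfg, reduced_cfg.simulation.n_lives_per_run,
                            run_seed(reduced_cfg.simulation.base_seed, 0))
        assert reps.n_runs == 1
        assert reps.summaries[0].total_months_diseased == direct.total_months_diseased

    def test_full_determinism(self, reduced_cfg):
        a = run_replicates(reduced_cfg)
        b = run_replicates(reduced_cfg)
        assert np.array_equal(a.burdens, b.burdens)

    def test_seed_derivation_is_order_invariant(self, reduced_cfg):
        # run 2 recomputed in isolation equals run 2 of the batch
        reps = run_replicates(reduced_cfg)
        alone = run_cohort(reduced_cfg, reduced_cfg.simulation.n_lives_per_run,
                           run_seed(reduced_cfg.simulation.base_seed, 2))
        assert reps.summaries[2].total_months_diseased == alone.total_months_diseased


class TestConfidenceInterval:
    def test_zero_spread(self):
        lo, hi = confidence_interval([0.095] * 1000)
        assert lo == hi == 0.095

    def test_uniform_grid_quantiles(self):
        lo, hi = confidence_interval(np.arange(1, 1001), level=0.95)
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_nesting(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=400)
        lo95, hi95 = confidence_interval(v, 0.95)
        lo99, hi99 = confidence_interval(v, 0.99)
        assert lo99 <= lo95 <= hi95 <= hi99

    def test_normal_method_close_to_percentile_for_gaussian(self):
        rng = np.random.default_rng(6)
        v = rng.normal(10, 2, size=20_000)
        p = confidence_interval(v, 0.95, "percentile")
        n = confidence_interval(v, 0.95, "normal")
        assert p[0] == pytest.approx(n[0], abs=0.1)
        assert p[1] == pytest.approx(n[1], abs=0.1)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            confidence_interval([1.0])


class TestAggregation:
    def test_merge_equals_concatenated_cohort(self, reduced_cfg):
        a = run_cohort(reduced_cfg, 400, 1)
        b = run_cohort(reduced_cfg, 600, 2)
        m = merge_summaries([a, b])
        assert m.n_lives == 1000
        assert m.total_months_diseased == a.total_months_diseased + b.total_months_diseased
        assert m.n_ever_depressed == a.n_ever_depressed + b.n_ever_depressed
        assert m.episode_count_distribution.sum() == 1000
        for k in ("chronic", "non_chronic"):
            assert len(m.episode_durations[k]) == \
                len(a.episode_durations[k]) + len(b.episode_durations[k])
        burden = ds.disease_burden(m)
        w_a = a.total_months_alive / m.total_months_alive
        assert burden == pytest.approx(
            w_a * ds.disease_burden(a) + (1 - w_a) * ds.disease_burden(b))

    def test_ci_width_shrinks_with_runs(self):
        cfg = make_reduced_config(horizon_months=120, monthly_onset=0.03,
                                  monthly_remission=0.08)
        cfg.simulation.n_lives_per_run = 100

        def width(n_runs, seed):
            cfg.simulation.n_runs = n_runs
            cfg.simulation.base_seed = seed
            lo, hi = confidence_interval(run_replicates(cfg).burdens, 0.95,
                                         method="mean")
            return hi - lo

        w100 = width(100, 10)
        w400 = width(400, 11)
        assert 0.3 < w400 / w100 < 0.8  # expected ~ 1/sqrt(4) = 0.5


class TestEngineAgreesWithLifecourse:
    """The vectorized engine and the per-life reference implementation are
    two routes through the same model; their cohort means must agree."""

    def test_mean_disease_burden_matches(self):
        cfg = make_reduced_config(horizon_months=240, monthly_onset=0.02,
                                  monthly_remission=0.06, mortality=0.001,
                                  services_off=False)
        n = 2500
        s = run_cohort(cfg, n, 123)
        eng_burden = s.total_months_diseased / s.total_months_alive
        eng_aff = s.n_ever_depressed / n

        rng = np.random.default_rng(321)
        lives = [simulate_life(cfg, rng) for _ in range(n)]
        dis = np.array([l.months_diseased for l in lives])
        alive = np.array([l.months_alive for l in lives])
        ref_burden = dis.sum() / alive.sum()
        ref_aff = np.mean([l.n_episodes > 0 for l in lives])

        se_b = dis.std() / alive.mean() / np.sqrt(n) * np.sqrt(2)
        se_a = np.sqrt(2 * ref_aff * (1 - ref_aff) / n)
        assert abs(eng_burden - ref_burden) < 4 * se_b
        assert abs(eng_aff - ref_aff) < 4 * se_a


class TestMarkovOracle:
    def test_two_state_occupancy_matches_matrix_iteration(self):
        """With constant onset/recurrence h1, constant remission h2, no
        services, no mortality and no history dependence, the model is a
        homogeneous 2-state chain; mean months diseased must match the
        occupancy from iterating the 2x2 transition matrix."""
        h1, h2, T = 0.03, 0.10, 240
        cfg = make_reduced_config(horizon_months=T, monthly_onset=h1,
                                  monthly_remission=h2)
        n = 100_000
        arrays = simulate_cohort(cfg, n, np.random.default_rng(2718))

        pi = np.array([1.0, 0.0])
        M = np.array([[1 - h1, h1], [h2, 1 - h2]])
        expected = 0.0
        for _ in range(T):
            expected += pi[1]
            pi = pi @ M
        mean_dis = arrays.months_diseased.mean()
        se = arrays.months_diseased.std() / np.sqrt(n)
        assert abs(mean_dis - expected) < 3 * se


class TestCalibrate:
    def test_empty_free_set_is_noop(self, reduced_cfg):
        out = calibrate(reduced_cfg, {}, {"lifetime_incidence": (0.5, 0.1)})
        assert out.course.incidence_scale == reduced_cfg.course.incidence_scale

    def test_recovers_known_incidence_scale(self):
        """Parameter recovery: generate a target statistic at a known scale,
        start the search elsewhere, and require the calibrated config to
        reproduce the target on a fresh seed."""
        cfg = make_reduced_config(horizon_months=600, monthly_onset=0.004,
                                  monthly_remission=0.06, mortality=0.0005,
                                  services_off=False)
        true = set_param(cfg, "course.incidence_scale", 0.5)
        from depsim.outcomes_metrics import plausibility_report
        target_inc = plausibility_report(run_cohort(true, 20_000, 777)).lifetime_incidence

        start = set_param(cfg, "course.incidence_scale", 1.0)
        out = calibrate(start, {"course.incidence_scale": (0.05, 1.0)},
                        {"lifetime_incidence": (target_inc, 0.004)},
                        n_lives=20_000, seed=555, max_iter=25)
        fresh = plausibility_report(run_cohort(out, 20_000, 999)).lifetime_incidence
        assert fresh == pytest.approx(target_inc, abs=0.012)
        assert out.course.incidence_scale == pytest.approx(0.5, abs=0.1)
        assert "calibration" in out.metadata

    def test_unreachable_target_raises_with_best_found(self, reduced_cfg):
        with pytest.raises(CalibrationError) as err:
            calibrate(reduced_cfg, {"course.incidence_scale": (0.9, 1.0)},
                      {"lifetime_incidence": (0.0001, 0.00001)},
                      n_lives=500, seed=3, max_iter=3)
        assert err.value.best is not None
        assert "lifetime_incidence" in err.value.achieved
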