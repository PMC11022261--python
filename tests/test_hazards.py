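import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import depsim as ds
from depsim.hazards import (HazardContext, mortality_hazard, onset_hazard,
                            recurrence_hazard, remission_hazard)
from depsim.params_config import set_param

from conftest import make_reduced_config


@pytest.fixture
def flat_cfg():
    # flat 1.14%/yr incidence at every age, no mortality inside the horizon
    return make_reduced_config(horizon_months=1200,
                               monthly_onset=1 - (1 - 0.0114) ** (1 / 12),
                               services_off=False)


class TestOnset:
    def test_flat_profile_monthly_value(self, flat_cfg):
        ctx = HazardContext(age_months=300)
        assert onset_hazard(ctx, flat_cfg) == pytest.approx(0.000955, abs=1e-5)

    def test_complete_prevention(self, flat_cfg):
        ctx = HazardContext(prevention_participant=True)
        cfg = set_param(flat_cfg, "services.prevention_effect", 1.0)
        assert onset_hazard(ctx, cfg) == 0.0

    def test_prevention_scales_by_one_minus_effect(self, flat_cfg):
        base = onset_hazard(HazardContext(age_months=100), flat_cfg)
        prevented = onset_hazard(
            HazardContext(age_months=100, prevention_participant=True), flat_cfg)
        assert prevented == pytest.approx(0.79 * base, rel=1e-12)

    def test_rejects_prior_episodes(self, flat_cfg):
        with pytest.raises(ValueError):
            onset_hazard(HazardContext(n_prior_episodes=1, months_in_remission=4),
                         flat_cfg)


class TestRecurrence:
    def test_first_month_one_prior(self, default_cfg):
        ctx = HazardContext(n_prior_episodes=1, months_in_remission=1)
        assert recurrence_hazard(ctx, default_cfg) == pytest.approx(0.0236, abs=1e-12)

    def test_first_month_two_priors(self, default_cfg):
        ctx = HazardContext(n_prior_episodes=2, months_in_remission=1)
        assert recurrence_hazard(ctx, default_cfg) == pytest.approx(0.0274, abs=5e-5)

    def test_full_aftercare_protection(self, default_cfg):
        cfg = set_param(default_cfg, "services.aftercare_effect", 1.0)
        ctx = HazardContext(n_prior_episodes=1, months_in_remission=1, in_aftercare=True)
        assert recurrence_hazard(ctx, cfg) == 0.0

    def test_rejects_never_ill(self, default_cfg):
        with pytest.raises(ValueError):
            recurrence_hazard(HazardContext(), default_cfg)

    def test_nondecreasing_in_prior_episodes(self, default_cfg):
        vals = [recurrence_hazard(
            HazardContext(n_prior_episodes=k, months_in_remission=6), default_cfg)
            for k in range(1, 30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] <= 1.0

    def test_nonincreasing_in_remission_time(self, default_cfg):
        vals = [recurrence_hazard(
            HazardContext(n_prior_episodes=2, months_in_remission=t), default_cfg)
            for t in range(1, 120)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))


class TestRemission:
    def test_untreated_monthly_base(self, default_cfg):
        ctx = HazardContext(currently_diseased=True, months_in_current_episode=4)
        assert remission_hazard(ctx, default_cfg) == pytest.approx(0.06098, abs=5e-5)

    def test_treated_monthly_and_cumulative(self, default_cfg):
        ctx = HazardContext(currently_diseased=True, months_in_current_episode=1,
                            in_treatment=True)
        p = remission_hazard(ctx, default_cfg)
        assert p == pytest.approx(0.0988, abs=2e-4)
        assert 1 - (1 - p) ** 12 == pytest.approx(0.713, abs=1e-3)

    def test_zero_effect_identity(self, default_cfg):
        cfg = set_param(default_cfg, "services.treatment_effect", 0.0)
        treated = remission_hazard(
            HazardContext(currently_diseased=True, months_in_current_episode=1,
                          in_treatment=True), cfg)
        assert treated == pytest.approx(0.06098, abs=5e-5)

    def test_rejects_healthy(self, default_cfg):
        with pytest.raises(ValueError):
            remission_hazard(HazardContext(), default_cfg)


class TestMortality:
    def test_baseline_identity(self, default_cfg):
        q = default_cfg.demography.monthly_mortality()
        ctx = HazardContext(age_months=600, sex=1)
        assert mortality_hazard(ctx, default_cfg) == q[600, 1]

    def test_excess_risk_is_multiplicative(self, reduced_cfg):
        reduced_cfg.demography._q_month[100, :] = 0.001
        reduced_cfg.demography.excess_mortality_rr = {"female": 2.0, "male": 2.0}
        ctx = HazardContext(age_months=100, currently_diseased=True,
                            months_in_current_episode=3, n_prior_episodes=1)
        assert mortality_hazard(ctx, reduced_cfg) == pytest.approx(0.002)

    def test_closed_cohort_at_max_age(self, default_cfg):
        last = default_cfg.demography.max_age_months - 1
        assert mortality_hazard(HazardContext(age_months=last), default_cfg) == 1.0
        with pytest.raises(ValueError):
            mortality_hazard(HazardContext(age_months=last + 1), default_cfg)


ctx_strategy = st.builds(
    HazardContext,
    age_months=st.integers(0, 1319),
    sex=st.sampled_from([0, 1]),
    n_prior_episodes=st.integers(1, 60),
    months_in_remission=st.integers(1, 600),
    in_treatment=st.booleans(),
    in_aftercare=st.booleans(),
    prevention_participant=st.booleans(),
)


class TestHazardBounds:
    """Every hazard stays a probability for any valid state and any
    service setting, including extreme multiplier sweeps."""

    @settings(max_examples=150, deadline=None)
    @given(ctx=ctx_strategy,
           eff=st.floats(0, 1), teff=st.floats(0, 20),
           base=st.floats(0, 1), mult=st.floats(1, 3))
    def test_all_hazards_in_unit_interval(self, default_cfg, ctx, eff, teff, base, mult):
        cfg = default_cfg.copy()
        cfg.services.prevention_effect = eff
        cfg.services.aftercare_effect = eff
        cfg.services.treatment_effect = teff
        cfg.course.recurrence_monthly_base = base
        cfg.course.episode_risk_multiplier = mult
        healthy_ctx = ctx
        assert 0 <= recurrence_hazard(healthy_ctx, cfg) <= 1
        diseased_ctx = HazardContext(
            age_months=ctx.age_months, sex=ctx.sex,
            n_prior_episodes=ctx.n_prior_episodes,
            months_in_current_episode=1, currently_diseased=True,
            in_treatment=ctx.in_treatment)
        assert 0 <= remission_hazard(diseased_ctx, cfg) <= 1
        assert 0 <= mortality_hazard(diseased_ctx, cfg) <= 1
        never_ill = HazardContext(age_months=ctx.age_months, sex=ctx.sex,
                                  prevention_participant=ctx.prevention_participant)
        assert 0 <= onset_hazard(never_ill, cfg) <= 1


def test_service_free_limit_equals_natural_course(default_cfg):
    """With zero reaches and zero effects every hazard equals the
    natural-course hazard."""
    cfg = ds.null_config(default_cfg)
    cfg.services.prevention_effect = 0.0
    cfg.services.treatment_effect = 0.0
    cfg.services.aftercare_effect = 0.0
    nat = ds.null_config(default_cfg)  # reaches 0, effects untouched
    for t in (1, 5, 24):
        ctx = HazardContext(n_prior_episodes=2, months_in_remission=t,
                            in_aftercare=True, prevention_participant=True)
        assert recurrence_hazard(ctx, cfg) == recurrence_hazard(
            HazardContext(n_prior_episodes=2, months_in_remission=t), nat)
    sick = HazardContext(currently_diseased=True, months_in_current_episode=3,
                         in_treatment=True, n_prior_episodes=1)
    assert remission_hazard(sick, cfg) == default_cfg.course.remission_monthly_base
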