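import numpy as np
import pytest

import depsim as ds
from depsim.params_config import DemographyParams


@pytest.fixture(scope="session")
def default_cfg():
    return ds.default_config()


def make_reduced_config(horizon_months=240, monthly_onset=0.02,
                        monthly_remission=0.06, monthly_recurrence=None,
                        mortality=0.0, services_off=True):
    """A small two-state test world: flat hazards, short horizon.

    ``monthly_recurrence=None`` uses ``monthly_onset`` with no episode
    multiplier and no decay, which collapses the model to a homogeneous
    2-state Markov chain (plus the closed-cohort death at the horizon).
    """
    cfg = ds.default_config()
    c = cfg.course
    c.yearly_incidence_overall = 1.0 - (1.0 - monthly_onset) ** 12
    c.incidence_scale = 1.0
    c.incidence_profile.age_bands = [0]
    c.incidence_profile.multipliers = [1.0]
    c.remission_monthly_base = monthly_remission
    c.remission_mode = "flat"
    c.recurrence_monthly_base = (monthly_onset if monthly_recurrence is None
                                 else monthly_recurrence)
    c.episode_risk_multiplier = 1.0 if monthly_recurrence is None else c.episode_risk_multiplier
    c.remission_decay.rate = 0.0 if monthly_recurrence is None else c.remission_decay.rate
    if services_off:
        cfg.services.prevention_reach = 0.0
        cfg.services.treatment_reach = 0.0
        cfg.services.aftercare_reach = 0.0
    d = cfg.demography
    d.max_age_months = horizon_months
    q = np.full((horizon_months, 2), mortality, dtype=float)
    q[-1, :] = 1.0
    d._q_month = q
    cfg.simulation.n_runs = 4
    cfg.simulation.n_lives_per_run = 200
    return cfg


@pytest.fixture
def reduced_cfg():
    return make_reduced_config()
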