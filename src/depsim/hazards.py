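"""Monthly transition probabilities as pure functions of state and config.

Every hazard is a probability per month, computed from a
:class:`HazardContext` (the fields of an individual's state that hazards may
depend on) and a :class:`~depsim.params_config.ModelConfig`.  Service
multipliers are applied last and the result is capped at
``course.max_hazard_cap`` (1 by default) in a single final step, so sweeps
that push multipliers high still yield valid probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params_config import FEMALE, MALE, ModelConfig, convert_probability

__all__ = ["HazardContext", "onset_hazard", "recurrence_hazard",
           "remission_hazard", "mortality_hazard"]


@dataclass
class HazardContext:
    """State fields a monthly transition probability may depend on.

    Exactly one of ``months_in_current_episode`` / ``months_in_remission``
    can be positive; both are 0 for a never-ill individual.
    """

    age_months: int = 0
    sex: int = FEMALE
    n_prior_episodes: int = 0
    months_in_current_episode: int = 0
    months_in_remission: int = 0
    in_treatment: bool = False
    in_aftercare: bool = False
    prevention_participant: bool = False
    currently_diseased: bool = False


def _cap(p: float, cfg: ModelConfig) -> float:
    return float(min(max(p, 0.0), cfg.course.max_hazard_cap))


def onset_hazard(ctx: HazardContext, cfg: ModelConfig) -> float:
    """Monthly first-onset probability for a never-ill individual.

    The yearly age/sex-profile incidence is converted to one month via the
    complement-power formula, then reduced by ``1 - prevention_effect`` for
    prevention participants.
    """
    if ctx.currently_diseased or ctx.n_prior_episodes > 0:
        raise ValueError("onset_hazard applies to never-ill individuals; "
                         "use recurrence_hazard after a first episode")
    c = cfg.course
    yearly = c.incidence_profile.yearly_by_age_month(
        c.yearly_incidence_overall, c.incidence_scale,
        cfg.demography.max_age_months)[ctx.age_months, ctx.sex]
    p = convert_probability(float(yearly), 12, 1)
    if ctx.prevention_participant:
        p *= 1.0 - cfg.services.prevention_effect
    return _cap(p, cfg)


def recurrence_hazard(ctx: HazardContext, cfg: ModelConfig) -> float:
    """Monthly recurrence probability for a remitted individual.

    ``base * multiplier**(n_episodes - 1) * decay(months_in_remission)``,
    reduced by ``1 - aftercare_effect`` during aftercare.  The decay factor
    is anchored at 1 for the first remission month, so the month-1 values
    (2.36% after one episode, 2.74% after two) hold for any decay rate.
    Prevention is applied here only when the config opts in
    (``services.prevention_applies_to_recurrence``).
    """
    if ctx.currently_diseased:
        raise ValueError("recurrence_hazard applies to healthy individuals")
    if ctx.n_prior_episodes < 1:
        raise ValueError("recurrence_hazard requires at least one prior episode")
    if ctx.months_in_remission < 1:
        raise ValueError("months_in_remission must be >= 1")
    c = cfg.course
    p = (c.recurrence_monthly_base
         * c.episode_risk_multiplier ** (ctx.n_prior_episodes - 1)
         * float(c.remission_decay.factor(ctx.months_in_remission)))
    if ctx.in_aftercare:
        p *= 1.0 - cfg.services.aftercare_effect
    if ctx.prevention_participant and cfg.services.prevention_applies_to_recurrence:
        p *= 1.0 - cfg.services.prevention_effect
    return _cap(p, cfg)


def remission_hazard(ctx: HazardContext, cfg: ModelConfig) -> float:
    """Monthly remission probability for a diseased individual.

    The spontaneous probability is flat (the 12-month milestone converted to
    one month, 6.098%) or piecewise in episode duration, multiplied by
    ``1 + treatment_effect`` while in treatment.
    """
    if not ctx.currently_diseased:
        raise ValueError("remission_hazard applies to diseased individuals")
    c = cfg.course
    if c.remission_mode == "flat":
        p = c.remission_monthly_base
    else:
        table = c.spontaneous_remission_by_duration(cfg.demography.max_age_months)
        p = float(table[min(max(ctx.months_in_current_episode, 1), len(table) - 1)])
    if ctx.in_treatment:
        p *= 1.0 + cfg.services.treatment_effect
    return _cap(p, cfg)


def mortality_hazard(ctx: HazardContext, cfg: ModelConfig) -> float:
    """Monthly death probability: the life-table entry for (age, sex),
    multiplied by the sex-specific excess-mortality relative risk during
    diseased months.  Equals 1 in the final model month (closed cohort)."""
    d = cfg.demography
    if not 0 <= ctx.age_months < d.max_age_months:
        raise ValueError(f"age {ctx.age_months} outside the life table "
                         f"[0, {d.max_age_months})")
    q = float(d.monthly_mortality()[ctx.age_months, ctx.sex])
    if ctx.currently_diseased:
        q *= float(d.rr_vector()[ctx.sex])
    return float(min(q, 1.0))
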