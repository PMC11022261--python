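"""Single-life simulation: monthly state transitions from birth to death.

This is the readable per-individual reference implementation of the model
dynamics.  Cohort-scale work goes through the vectorized engine in
:mod:`depsim.engine`, which applies the identical event order; the two are
cross-checked statistically in the test suite.

Event order within a month (fixed; the model is defined at monthly
resolution and simultaneous events must be serialized):

1. mortality draw — a death ends the month, no further transitions;
2. if diseased: remission draw (treatment multiplier applies if the
   individual is in treatment this month), then care-pathway progression
   (treatment month counter, waiting countdown, help-seeking draw);
3. if healthy: first-onset draw (never ill) or recurrence draw (>= 1 prior
   episode), then the aftercare month counter;
4. age advances one month.

Occupancy accounting: an individual occupies exactly one state per lived
month, the state held at the start of the month.  A first-onset draw that
succeeds in month *m* makes the individual diseased from month *m + 1*
onward; a remission draw that succeeds in month *m* ends an episode whose
duration includes month *m*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hazards
from .params_config import FEMALE, MALE, ModelConfig

__all__ = ["IndividualState", "EpisodeRecord", "LifeRecord", "step_month",
           "draw_waiting_time", "simulate_life", "classify_chronicity",
           "PATHWAY_NONE", "PATHWAY_WAITING", "PATHWAY_TREATMENT",
           "PATHWAY_AFTERCARE"]

PATHWAY_NONE = "none"
PATHWAY_WAITING = "waiting"
PATHWAY_TREATMENT = "in_treatment"
PATHWAY_AFTERCARE = "in_aftercare"


@dataclass
class EpisodeRecord:
    start_month: int          # age (months) of the first diseased month
    duration: int             # months diseased, truncated at death
    treated: bool             # treatment started during this episode
    ended_by: str             # "remission" | "death"


@dataclass
class IndividualState:
    """Full per-person state; the hazard-relevant subset mirrors
    :class:`~depsim.hazards.HazardContext`."""

    sex: int = FEMALE
    age_months: int = 0
    alive: bool = True
    currently_diseased: bool = False
    n_episodes: int = 0                    # episodes started so far
    months_in_current_episode: int = 0     # months diseased incl. current
    months_in_remission: int = 0
    pathway: str = PATHWAY_NONE
    waiting_months_left: int = 0
    treatment_months_done: int = 0
    aftercare_months_done: int = 0
    prevention_participant: bool = False
    treated_current_episode: bool = False
    ever_treated: bool = False
    episode_start_month: int = -1
    episodes: list = field(default_factory=list)

    def hazard_context(self) -> hazards.HazardContext:
        return hazards.HazardContext(
            age_months=self.age_months,
            sex=self.sex,
            n_prior_episodes=self.n_episodes if not self.currently_diseased else self.n_episodes - 1,
            months_in_current_episode=self.months_in_current_episode,
            months_in_remission=self.months_in_remission,
            in_treatment=self.pathway == PATHWAY_TREATMENT,
            in_aftercare=self.pathway == PATHWAY_AFTERCARE,
            prevention_participant=self.prevention_participant,
            currently_diseased=self.currently_diseased,
        )


@dataclass
class LifeRecord:
    """A completed simulated life."""

    sex: int
    months_alive: int
    months_diseased: int
    episodes: list
    ever_treated: bool

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)


def draw_waiting_time(cfg: ModelConfig, rng: np.random.Generator) -> int:
    """Months between help-seeking and treatment start: a normal draw
    (mean 5, SD 1 by default) rounded to the nearest integer and truncated
    below at 0."""
    s = cfg.services
    w = rng.normal(s.waiting_mean, s.waiting_sd)
    return max(0, int(round(w)))


def _close_episode(state: IndividualState, ended_by: str) -> None:
    state.episodes.append(EpisodeRecord(
        start_month=state.episode_start_month,
        duration=state.months_in_current_episode,
        treated=state.treated_current_episode,
        ended_by=ended_by,
    ))


def _start_episode(state: IndividualState) -> None:
    state.currently_diseased = True
    state.n_episodes += 1
    state.months_in_current_episode = 0     # becomes 1 in the next month
    state.months_in_remission = 0
    state.treated_current_episode = False
    state.episode_start_month = state.age_months + 1
    if state.pathway == PATHWAY_AFTERCARE:  # recurrence ends aftercare
        state.pathway = PATHWAY_NONE
        state.aftercare_months_done = 0


def _start_treatment(state: IndividualState) -> None:
    state.pathway = PATHWAY_TREATMENT
    state.treatment_months_done = 0
    state.treated_current_episode = True
    state.ever_treated = True


def step_month(state: IndividualState, cfg: ModelConfig,
               rng: np.random.Generator) -> IndividualState:
    """Advance one individual by one month; returns a new state object.

    The returned state reflects the situation at the start of the next
    month.  Raises if called on a dead state.
    """
    if not state.alive:
        raise ValueError("step_month called on a dead individual")
    s = replace(state, episodes=list(state.episodes))
    svc = cfg.services

    # month-start counter ageing: duration/remission clocks include this month
    if s.currently_diseased:
        s.months_in_current_episode += 1
    elif s.n_episodes > 0:
        s.months_in_remission += 1

    # (1) mortality
    if rng.random() < hazards.mortality_hazard(s.hazard_context(), cfg):
        s.alive = False
        if s.currently_diseased:
            _close_episode(s, "death")
        s.age_months += 1
        return s

    if s.currently_diseased:
        # (2) remission draw with the current treatment status
        if rng.random() < hazards.remission_hazard(s.hazard_context(), cfg):
            _close_episode(s, "remission")
            s.currently_diseased = False
            s.months_in_current_episode = 0
            s.months_in_remission = 0           # becomes 1 next month
            if s.pathway == PATHWAY_TREATMENT and rng.random() < svc.aftercare_reach:
                s.pathway = PATHWAY_AFTERCARE
                s.aftercare_months_done = 0
            else:
                s.pathway = PATHWAY_NONE
            s.waiting_months_left = 0
        else:
            # pathway progression for a still-diseased month
            if s.pathway == PATHWAY_TREATMENT:
                s.treatment_months_done += 1
                if s.treatment_months_done >= svc.treatment_max_duration:
                    s.pathway = PATHWAY_NONE    # revert to untreated-diseased
            elif s.pathway == PATHWAY_WAITING:
                s.waiting_months_left -= 1
                if s.waiting_months_left <= 0:
                    _start_treatment(s)
            if s.pathway == PATHWAY_NONE and not (
                    svc.retreatment_lockout and s.treated_current_episode):
                if rng.random() < svc.monthly_seek_probability:
                    w = draw_waiting_time(cfg, rng)
                    if svc.retreatment == "no_wait" and s.ever_treated:
                        w = 0
                    if w == 0:
                        _start_treatment(s)
                    else:
                        s.pathway = PATHWAY_WAITING
                        s.waiting_months_left = w
    else:
        # (3) healthy: onset or recurrence, then the aftercare clock
        if s.n_episodes == 0:
            if rng.random() < hazards.onset_hazard(s.hazard_context(), cfg):
                _start_episode(s)
        else:
            if rng.random() < hazards.recurrence_hazard(s.hazard_context(), cfg):
                _start_episode(s)
                if svc.retreatment == "immediate" and s.ever_treated:
                    _start_treatment(s)
            elif s.pathway == PATHWAY_AFTERCARE:
                s.aftercare_months_done += 1
                if s.aftercare_months_done >= svc.aftercare_max_duration:
                    s.pathway = PATHWAY_NONE

    # (4) ageing
    s.age_months += 1
    return s


def simulate_life(cfg: ModelConfig, rng: np.random.Generator,
                  event_log: list | None = None) -> LifeRecord:
    """Simulate one life from birth until death or the model age limit.

    ``event_log``, if given, receives one dict per lived month (age, state,
    pathway) — a debugging aid, off by default.
    """
    state = IndividualState(
        sex=FEMALE if rng.random() < cfg.demography.sex_ratio_at_entry else MALE,
        prevention_participant=rng.random() < cfg.services.prevention_reach,
    )
    months_alive = 0
    months_diseased = 0
    while state.alive and state.age_months < cfg.demography.max_age_months:
        months_alive += 1
        if state.currently_diseased:
            months_diseased += 1
        if event_log is not None:
            event_log.append({
                "age_months": state.age_months,
                "state": "diseased" if state.currently_diseased else "healthy",
                "pathway": state.pathway,
                "n_episodes": state.n_episodes,
            })
        state = step_month(state, cfg, rng)
    if state.alive and state.currently_diseased:
        # horizon reached while diseased (only possible if the life table
        # does not close the cohort); truncate like a death
        _close_episode(state, "death")
    return LifeRecord(
        sex=state.sex,
        months_alive=months_alive,
        months_diseased=months_diseased,
        episodes=state.episodes,
        ever_treated=state.ever_treated,
    )


def classify_chronicity(life: LifeRecord) -> str:
    """``chronic`` if any episode lasted longer than 24 months or the life
    had three or more episodes; ``never_ill`` without any episode;
    ``non_chronic`` otherwise."""
    if life.n_episodes == 0:
        return "never_ill"
    if life.n_episodes >= 3 or any(e.duration > 24 for e in life.episodes):
        return "chronic"
    return "non_chronic"
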