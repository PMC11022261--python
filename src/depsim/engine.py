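"""Vectorized cohort engine.

Simulates all lives of one cohort synchronously, month by month, with numpy
array operations.  Everyone enters at age 0, so the loop index is both
calendar month and age.  The event order per month is identical to
:func:`depsim.lifecourse.step_month` (mortality, then remission and the care
pathway, then onset/recurrence and the aftercare clock, then ageing).

Random-number consumption is state-independent: every month consumes one
``(5, n)`` uniform block (mortality, remission, help-seeking,
onset/recurrence, aftercare routing) and one length-``n`` normal block
(waiting times), whether or not the draws are used.  Two runs started from
the same seed therefore consume identical streams regardless of the service
parameters, which is what makes common random numbers work: paired
scenario/null cohorts differ only where a threshold differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params_config import ModelConfig

__all__ = ["CohortArrays", "simulate_cohort"]

_NONE, _WAIT, _TREAT, _AFTER = 0, 1, 2, 3


@dataclass
class CohortArrays:
    """Per-life results of one simulated cohort."""

    sex: np.ndarray                 # int8, 0 female / 1 male
    months_alive: np.ndarray        # int32
    months_diseased: np.ndarray     # int32
    n_episodes: np.ndarray          # int16, episodes started (incl. truncated)
    max_episode_duration: np.ndarray  # int16, 0 if never ill
    ever_treated: np.ndarray        # bool
    episode_durations: np.ndarray   # int32, one entry per completed episode
    episode_life_index: np.ndarray  # int32, owning life of each duration


def simulate_cohort(cfg: ModelConfig, n_lives: int,
                    rng: np.random.Generator) -> CohortArrays:
    if n_lives == 0:
        z = np.zeros(0, dtype=np.int32)
        return CohortArrays(z.astype(np.int8), z, z, z.astype(np.int16),
                            z.astype(np.int16), z.astype(bool), z, z)

    c, svc, dem = cfg.course, cfg.services, cfg.demography
    T = dem.max_age_months
    n = int(n_lives)

    # per-month lookups ---------------------------------------------------
    q_base = dem.monthly_mortality()                       # (T, 2)
    rr = dem.rr_vector()                                   # (2,)
    yearly = c.incidence_profile.yearly_by_age_month(
        c.yearly_incidence_overall, c.incidence_scale, T)  # (T, 2)
    p_onset = -np.expm1(np.log1p(-np.minimum(yearly, 1.0 - 1e-15)) / 12.0)
    h_spont = c.spontaneous_remission_by_duration(T)       # by episode month
    treat_mult = 1.0 + svc.treatment_effect
    p_seek = svc.monthly_seek_probability
    prev_factor = 1.0 - svc.prevention_effect
    after_factor = 1.0 - svc.aftercare_effect
    cap = c.max_hazard_cap
    log_mult = np.log(c.episode_risk_multiplier)
    decay_rate = c.remission_decay.rate if c.remission_decay.form == "exponential" else 0.0

    # state ----------------------------------------------------------------
    u0 = rng.random(n)
    sex = np.where(u0 < dem.sex_ratio_at_entry, 0, 1).astype(np.int8)
    prevention = rng.random(n) < svc.prevention_reach

    alive = np.ones(n, dtype=bool)
    diseased = np.zeros(n, dtype=bool)
    n_ep = np.zeros(n, dtype=np.int16)
    m_ep = np.zeros(n, dtype=np.int32)      # months in current episode
    m_rem = np.zeros(n, dtype=np.int32)     # months in remission
    pathway = np.zeros(n, dtype=np.int8)
    wait_left = np.zeros(n, dtype=np.int32)
    treat_m = np.zeros(n, dtype=np.int32)
    after_m = np.zeros(n, dtype=np.int32)
    treated_cur = np.zeros(n, dtype=bool)
    ever_treated = np.zeros(n, dtype=bool)

    months_alive = np.zeros(n, dtype=np.int32)
    months_diseased = np.zeros(n, dtype=np.int32)
    dur_chunks: list[np.ndarray] = []
    id_chunks: list[np.ndarray] = []
    idx = np.arange(n, dtype=np.int32)

    for month in range(T):
        if not alive.any():
            break
        # occupancy bookkeeping (state held at the start of the month)
        months_alive[alive] += 1
        dis0 = alive & diseased
        months_diseased[dis0] += 1
        m_ep[dis0] += 1
        healthy0 = alive & ~diseased
        prior0 = healthy0 & (n_ep > 0)
        m_rem[prior0] += 1

        U = rng.random((5, n))
        Z = rng.normal(size=n)

        # (1) mortality ----------------------------------------------------
        q = q_base[month][sex]
        q = np.where(diseased, np.minimum(q * rr[sex], 1.0), q)
        die = alive & (U[0] < q)
        died_dis = die & diseased
        if died_dis.any():
            dur_chunks.append(m_ep[died_dis].copy())
            id_chunks.append(idx[died_dis])
        alive = alive & ~die

        # (2) diseased: remission, then pathway progression -----------------
        D = alive & dis0
        h = h_spont[np.minimum(m_ep, len(h_spont) - 1)]
        h = np.where(pathway == _TREAT, h * treat_mult, h)
        np.minimum(h, cap, out=h)
        remit = D & (U[1] < h)
        if remit.any():
            dur_chunks.append(m_ep[remit].copy())
            id_chunks.append(idx[remit])
            to_after = remit & (pathway == _TREAT) & (U[4] < svc.aftercare_reach)
            diseased[remit] = False
            m_ep[remit] = 0
            m_rem[remit] = 0
            treated_cur[remit] = False
            pathway[remit] = _NONE
            wait_left[remit] = 0
            pathway[to_after] = _AFTER
            after_m[to_after] = 0

        D2 = D & ~remit
        in_tr = D2 & (pathway == _TREAT)
        treat_m[in_tr] += 1
        term = in_tr & (treat_m >= svc.treatment_max_duration)
        pathway[term] = _NONE
        in_wait = D2 & (pathway == _WAIT)
        wait_left[in_wait] -= 1
        start = in_wait & (wait_left <= 0)
        pathway[start] = _TREAT
        treat_m[start] = 0
        treated_cur[start] = True
        ever_treated[start] = True
        eligible = D2 & (pathway == _NONE)
        if svc.retreatment_lockout:
            eligible &= ~treated_cur
        seek = eligible & (U[2] < p_seek)
        if seek.any():
            w = np.maximum(0, np.rint(svc.waiting_mean + svc.waiting_sd * Z)).astype(np.int32)
            if svc.retreatment == "no_wait":
                w = np.where(ever_treated, 0, w)
            s_now = seek & (w == 0)
            s_wait = seek & (w > 0)
            pathway[s_now] = _TREAT
            treat_m[s_now] = 0
            treated_cur[s_now] = True
            ever_treated[s_now] = True
            pathway[s_wait] = _WAIT
            wait_left[s_wait] = w[s_wait]

        # (3) healthy: onset / recurrence, aftercare clock -------------------
        H = alive & healthy0
        Hn = H & (n_ep == 0)
        po = p_onset[month][sex]
        po = np.where(prevention, po * prev_factor, po)
        np.minimum(po, cap, out=po)
        onset = Hn & (U[3] < po)

        Hp = H & (n_ep > 0)
        hr = c.recurrence_monthly_base * np.exp(
            log_mult * (n_ep - 1) - decay_rate * np.maximum(m_rem - 1, 0))
        hr = np.where(pathway == _AFTER, hr * after_factor, hr)
        if svc.prevention_applies_to_recurrence:
            hr = np.where(prevention, hr * prev_factor, hr)
        np.minimum(hr, cap, out=hr)
        recur = Hp & (U[3] < hr)

        new_ep = onset | recur
        if new_ep.any():
            diseased[new_ep] = True
            n_ep[new_ep] += 1
            m_ep[new_ep] = 0
            m_rem[new_ep] = 0
            treated_cur[new_ep] = False
            pathway[new_ep] = _NONE
            after_m[new_ep] = 0
            if svc.retreatment == "immediate":
                # established care: ever-treated relapsers restart treatment
                # in the first month of the new episode, no seek/wait
                re_tr = recur & ever_treated
                pathway[re_tr] = _TREAT
                treat_m[re_tr] = 0
                treated_cur[re_tr] = True

        ac = Hp & ~recur & (pathway == _AFTER)
        after_m[ac] += 1
        done = ac & (after_m >= svc.aftercare_max_duration)
        pathway[done] = _NONE

    if dur_chunks:
        durations = np.concatenate(dur_chunks).astype(np.int32)
        life_index = np.concatenate(id_chunks).astype(np.int32)
    else:
        durations = np.zeros(0, dtype=np.int32)
        life_index = np.zeros(0, dtype=np.int32)

    max_dur = np.zeros(n, dtype=np.int32)
    np.maximum.at(max_dur, life_index, durations)

    return CohortArrays(
        sex=sex,
        months_alive=months_alive,
        months_diseased=months_diseased,
        n_episodes=n_ep,
        max_episode_duration=max_dur.astype(np.int16),
        ever_treated=ever_treated,
        episode_durations=durations,
        episode_life_index=life_index,
    )
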