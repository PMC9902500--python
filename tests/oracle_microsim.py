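"""Independent patient-level Monte-Carlo oracle for the cohort engine.

Simulates individual patients through the same generative process the
cohort algebra integrates: each alive patient-year, a categorical draw over
{event of type k (fatal with the type's case fatality), residual non-event
death, stay}, with GI bleeding returning survivors to event-free AF and the
ablation arm passing through the periprocedural tree first. Implemented
from the model parameters directly, without using the package's transition
matrix, so it can serve as the correctness oracle for the transition
algebra.
"""

from __future__ import annotations

import numpy as np

from afibcea.params import EVENT_TYPES, ModelParams

# state codes mirror afibcea.markov.HealthState by value
FREE, GI_T, DEAD = 0, 5, 11
ACUTE = {"HF_HOSP": 1, "MI": 2, "ISCHEMIC_STROKE": 3, "ICH": 4, "GI_BLEED": 5}
POST = {"HF_HOSP": 6, "MI": 7, "ISCHEMIC_STROKE": 8, "ICH": 9}
POST_PROC = 10
N_STATES = 12


def simulate_occupancy(
    params: ModelParams, arm: str, n_patients: int, seed: int
) -> np.ndarray:
    """Fraction of patients in each state at each cycle, shape (H+1, 12)."""
    rng = np.random.default_rng(seed)
    horizon = params.horizon
    state = np.zeros(n_patients, dtype=np.int8)

    if arm == "ablation":
        u = rng.random(n_patients)
        p_stroke = params.proc_stroke.prob
        p_tamp = params.proc_tamponade.prob
        p_death = params.proc_death.prob
        f_proc = params.fatality["PROC_STROKE_TIA"].prob
        stroke = u < p_stroke
        death = (u >= p_stroke) & (u < p_stroke + p_death)
        # tamponade and no-complication both land in event-free AF
        state[stroke] = POST_PROC
        state[stroke & (rng.random(n_patients) < f_proc)] = DEAD
        state[death] = DEAD

    p = np.array([params.event_probs[arm][ev].prob for ev in EVENT_TYPES])
    f = np.array([params.fatality[ev].prob for ev in EVENT_TYPES])
    resid = max(0.0, params.mortality[arm].prob - float(p @ f))
    death_hazard = float(p @ f) + resid

    # categorical outcome per alive patient-year:
    # [event_0 .. event_4, residual death, stay]
    cuts = np.concatenate([np.cumsum(p), [p.sum() + resid]])
    acute_code = np.array([ACUTE[ev] for ev in EVENT_TYPES], dtype=np.int8)
    stay_code = np.arange(N_STATES, dtype=np.int8)  # stay target by current state
    for ev, ac in ACUTE.items():
        stay_code[ac] = POST.get(ev, FREE)  # acute year -> post state (GI -> free)
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0] = np.bincount(state, minlength=N_STATES) / n_patients

    for t in range(1, horizon + 1):
        alive = state != DEAD
        gi = state == GI_T
        regular = alive & ~gi
        new = state.copy()
        # GI transient: survivors return to event-free AF
        u = rng.random(n_patients)
        new[gi] = np.where(u[gi] < death_hazard, DEAD, FREE)
        idx = np.flatnonzero(regular)
        cat = np.searchsorted(cuts, u[idx], side="right")  # 0..4 events, 5 death, 6 stay
        out = stay_code[state[idx]]
        is_event = cat < len(EVENT_TYPES)
        ev_cat = cat[is_event]
        fatal = rng.random(ev_cat.size) < f[ev_cat]
        ev_state = acute_code[ev_cat].copy()
        ev_state[fatal] = DEAD
        out = out.astype(np.int8)
        out[is_event] = ev_state
        out[cat == len(EVENT_TYPES)] = DEAD
        new[idx] = out
        state = new
        occ[t] = np.bincount(state, minlength=N_STATES) / n_patients
    return occ
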