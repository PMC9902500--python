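"""Annual-cycle Markov cohort engine for the two rhythm-control strategies.

State space
-----------
The cohort occupies twelve states: event-free AF; five acute event states
(the year in which a heart-failure hospitalisation, MI, ischaemic stroke,
ICH or GI bleed occurs); four chronic post-event states; a post
periprocedural-stroke state (ablation arm only); and death. GI bleeding is
transient — survivors return to event-free AF the following cycle — so it
has an acute state but no post state.

Transition algebra
------------------
From every alive state the cohort faces competing annual risks: the five
arm-specific event probabilities (an event of type *k* is fatal with its
case-fatality probability, otherwise moves the patient to the acute state
of *k*), plus a residual non-event death probability. Because the reported
annual all-cause mortality already contains event-attributable deaths, the
residual is ``max(0, all_cause - sum_k p_k * fatality_k)`` — subtracting
the expected event-death mass avoids double counting. Patients in a
post-event state who suffer a different event move through that event's
acute state (most-recent-event dominance).

Accrual and discounting
-----------------------
Cycles are one year with no half-cycle correction. Costs and QALYs accrue
on the end-of-cycle state occupancy and are discounted at
``1 / (1 + r)^t`` with ``t = 1`` for the first year; the ablation arm's
periprocedural decision tree executes before the first cycle at exponent 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .params import ARMS, EVENT_TYPES, ModelParams, ParamError


class HealthState(IntEnum):
    """Markov states; values index the occupancy vector."""

    EVENT_FREE_AF = 0
    ACUTE_HF = 1
    ACUTE_MI = 2
    ACUTE_STROKE = 3
    ACUTE_ICH = 4
    GI_BLEED_TRANSIENT = 5
    POST_HF = 6
    POST_MI = 7
    POST_STROKE = 8
    POST_ICH = 9
    POST_PROC_STROKE = 10
    DEAD = 11


N_STATES = len(HealthState)

#: Acute destination of each event type.
ACUTE_STATE = {
    "HF_HOSP": HealthState.ACUTE_HF,
    "MI": HealthState.ACUTE_MI,
    "ISCHEMIC_STROKE": HealthState.ACUTE_STROKE,
    "ICH": HealthState.ACUTE_ICH,
    "GI_BLEED": HealthState.GI_BLEED_TRANSIENT,
}

#: Chronic state following each acute event year (GI bleeding recovers).
POST_STATE = {
    "HF_HOSP": HealthState.POST_HF,
    "MI": HealthState.POST_MI,
    "ISCHEMIC_STROKE": HealthState.POST_STROKE,
    "ICH": HealthState.POST_ICH,
}

#: Utility key of each state (None -> dead, utility 0).
_STATE_UTILITY_KEY = {
    HealthState.EVENT_FREE_AF: "EVENT_FREE",
    HealthState.ACUTE_HF: "HF_HOSP",
    HealthState.ACUTE_MI: "MI",
    HealthState.ACUTE_STROKE: "ISCHEMIC_STROKE",
    HealthState.ACUTE_ICH: "ICH",
    HealthState.GI_BLEED_TRANSIENT: "EVENT_FREE",  # GI bleed utility = event-free
    HealthState.POST_HF: "HF_HOSP",
    HealthState.POST_MI: "MI",
    HealthState.POST_STROKE: "ISCHEMIC_STROKE",
    HealthState.POST_ICH: "ICH",
    HealthState.POST_PROC_STROKE: "ISCHEMIC_STROKE",
    HealthState.DEAD: None,
}

_ACUTE_COST_EVENT = {
    HealthState.ACUTE_HF: "HF_HOSP",
    HealthState.ACUTE_MI: "MI",
    HealthState.ACUTE_STROKE: "ISCHEMIC_STROKE",
    HealthState.ACUTE_ICH: "ICH",
    HealthState.GI_BLEED_TRANSIENT: "GI_BLEED",
}

_POST_COST_EVENT = {
    HealthState.POST_HF: "HF_HOSP",
    HealthState.POST_MI: "MI",
    HealthState.POST_STROKE: "ISCHEMIC_STROKE",
    HealthState.POST_ICH: "ICH",
}


@dataclass
class ArmResult:
    """Discounted totals and the per-cycle trace for one strategy."""

    arm: str
    total_cost: float
    total_qaly: float
    trace: pd.DataFrame  # cycle x (state occupancies, cost, qaly, discounted)

    def summary(self) -> dict:
        return {
            "arm": self.arm,
            "total_cost": self.total_cost,
            "total_qaly": self.total_qaly,
        }


def discount(value: float, rate: float, cycle: int) -> float:
    """Present value of ``value`` accrued at ``cycle`` (years from start)."""
    if rate < 0:
        raise ParamError("discount rate must be >= 0")
    if cycle < 0:
        raise ParamError("cycle index must be >= 0")
    return value / (1.0 + rate) ** cycle


def residual_mortality(params: ModelParams, arm: str) -> float:
    """Non-event annual death probability after removing event deaths."""
    p = params.event_probs[arm]
    event_deaths = sum(p[ev].prob * params.fatality[ev].prob for ev in EVENT_TYPES)
    return max(0.0, params.mortality[arm].prob - event_deaths)


def transition_matrix(params: ModelParams, arm: str) -> np.ndarray:
    """Row-stochastic annual transition matrix for one strategy."""
    if arm not in ARMS:
        raise ParamError(f"unknown arm {arm!r}; expected one of {ARMS}")
    p = {ev: params.event_probs[arm][ev].prob for ev in EVENT_TYPES}
    f = {ev: params.fatality[ev].prob for ev in EVENT_TYPES}
    resid = residual_mortality(params, arm)
    total_event = sum(p.values())
    death_hazard = sum(p[ev] * f[ev] for ev in EVENT_TYPES) + resid
    stay = 1.0 - total_event - resid
    if stay < -1e-12:
        raise ParamError(
            f"arm {arm!r}: competing risks sum to {total_event + resid:.4f} > 1"
        )

    T = np.zeros((N_STATES, N_STATES))
    stay_target = {
        HealthState.EVENT_FREE_AF: HealthState.EVENT_FREE_AF,
        HealthState.ACUTE_HF: HealthState.POST_HF,
        HealthState.ACUTE_MI: HealthState.POST_MI,
        HealthState.ACUTE_STROKE: HealthState.POST_STROKE,
        HealthState.ACUTE_ICH: HealthState.POST_ICH,
        HealthState.POST_HF: HealthState.POST_HF,
        HealthState.POST_MI: HealthState.POST_MI,
        HealthState.POST_STROKE: HealthState.POST_STROKE,
        HealthState.POST_ICH: HealthState.POST_ICH,
        HealthState.POST_PROC_STROKE: HealthState.POST_PROC_STROKE,
    }
    for s, target in stay_target.items():
        T[s, HealthState.DEAD] += resid
        for ev in EVENT_TYPES:
            T[s, HealthState.DEAD] += p[ev] * f[ev]
            T[s, ACUTE_STATE[ev]] += p[ev] * (1.0 - f[ev])
        T[s, target] += stay
    # GI-bleed transient contract: survivors return to event-free AF.
    gi = HealthState.GI_BLEED_TRANSIENT
    T[gi, HealthState.DEAD] = death_hazard
    T[gi, HealthState.EVENT_FREE_AF] = 1.0 - death_hazard
    T[HealthState.DEAD, HealthState.DEAD] = 1.0
    assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)
    return T


def state_costs(params: ModelParams, arm: str) -> np.ndarray:
    """Annual cost attached to each state under the configured convention."""
    c = np.zeros(N_STATES)
    free = params.event_free_cost[arm]
    c[HealthState.EVENT_FREE_AF] = free
    for state, ev in _ACUTE_COST_EVENT.items():
        c[state] = params.event_costs[arm][ev]
    for state, ev in _POST_COST_EVENT.items():
        c[state] = params.event_costs[arm][ev] if params.post_event_cost == "event" else free
    c[HealthState.POST_PROC_STROKE] = params.post_proc_stroke_annual_cost
    return c


def state_utilities(params: ModelParams) -> np.ndarray:
    u = np.zeros(N_STATES)
    for state, key in _STATE_UTILITY_KEY.items():
        u[state] = params.utilities[key].value if key is not None else 0.0
    return u


def run_periprocedural_tree(params: ModelParams) -> tuple[np.ndarray, float]:
    """Split the entering ablation cohort through the procedure tree.

    Returns the post-tree state distribution and the expected one-off
    procedure cost. Periprocedural deaths and fatal periprocedural strokes
    go to ``DEAD``; surviving stroke patients to ``POST_PROC_STROKE``;
    tamponade (after its one-off cost) and uncomplicated procedures to
    event-free AF. The death branch carries the no-complication procedure
    cost (the procedure was performed).
    """
    p_stroke = params.proc_stroke.prob
    p_tamp = params.proc_tamponade.prob
    p_death = params.proc_death.prob
    if p_stroke + p_tamp + p_death > 1.0 + 1e-12:
        raise ParamError("periprocedural branch probabilities sum to > 1")
    f_stroke = params.fatality["PROC_STROKE_TIA"].prob

    dist = np.zeros(N_STATES)
    dist[HealthState.DEAD] = p_death + p_stroke * f_stroke
    dist[HealthState.POST_PROC_STROKE] = p_stroke * (1.0 - f_stroke)
    dist[HealthState.EVENT_FREE_AF] = 1.0 - dist[HealthState.DEAD] - dist[
        HealthState.POST_PROC_STROKE
    ]
    upfront = (
        (1.0 - p_stroke - p_tamp) * params.procedure_costs["no_complication"]
        + p_stroke * params.procedure_costs["PROC_STROKE_TIA"]
        + p_tamp * params.procedure_costs["TAMPONADE"]
    )
    return dist, upfront


def step_cycle(
    dist: np.ndarray, arm: str, params: ModelParams
) -> tuple[np.ndarray, float, float]:
    """Advance one annual cycle; return (new distribution, cost, QALY).

    Cost and QALY are undiscounted and evaluated on the end-of-cycle
    occupancy.
    """
    if not np.isclose(dist.sum(), 1.0, atol=1e-9) or (dist < -1e-12).any():
        raise ParamError("state distribution must be non-negative and sum to 1")
    T = transition_matrix(params, arm)
    new = dist @ T
    cost = float(new @ state_costs(params, arm))
    qaly = float(new @ state_utilities(params))
    return new, cost, qaly


def run_markov(arm: str, params: ModelParams) -> ArmResult:
    """Evolve one strategy over the full horizon, accruing discounted totals."""
    if arm not in ARMS:
        raise ParamError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if params.horizon < 1:
        raise ParamError("horizon must be at least one cycle")

    if arm == "ablation":
        dist, upfront = run_periprocedural_tree(params)
    else:
        dist = np.zeros(N_STATES)
        dist[HealthState.EVENT_FREE_AF] = 1.0
        upfront = 0.0

    T = transition_matrix(params, arm)
    costs = state_costs(params, arm)
    utils = state_utilities(params)
    rate = params.discount_rate

    rows = []
    rows.append(
        {"cycle": 0, "cost": upfront, "qaly": 0.0, "disc_cost": upfront, "disc_qaly": 0.0}
        | {st.name: dist[st] for st in HealthState}
    )
    total_cost, total_qaly = upfront, 0.0
    for t in range(1, params.horizon + 1):
        dist = dist @ T
        cost = float(dist @ costs)
        qaly = float(dist @ utils)
        dc = discount(cost, rate, t)
        dq = discount(qaly, rate, t)
        total_cost += dc
        total_qaly += dq
        rows.append(
            {"cycle": t, "cost": cost, "qaly": qaly, "disc_cost": dc, "disc_qaly": dq}
            | {st.name: dist[st] for st in HealthState}
        )
    trace = pd.DataFrame(rows).set_index("cycle")
    return ArmResult(arm=arm, total_cost=total_cost, total_qaly=total_qaly, trace=trace)


def run_both_arms(params: ModelParams) -> dict[str, ArmResult]:
    """Convenience wrapper returning results keyed by arm."""
    return {arm: run_markov(arm, params) for arm in ARMS}
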