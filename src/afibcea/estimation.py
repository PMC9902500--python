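"""Estimate model parameters from arm-labelled patient-level records.

Produces the count-based parameter blocks the Markov model consumes:
per-arm first-year event probabilities (numerator = patients with at least
one event of the type in days [0, 365), denominator = arm size, with
periprocedural deaths removed from the ablation denominator), case
fatality per event type pooled over arms, annual all-cause mortality, and
mean annual costs per event type and arm. Utilities, procedure costs and
maintenance costs are not observable in the event schema and are carried
over from a base parameter set (the packaged defaults by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    ARMS,
    EVENT_TYPES,
    CountProb,
    ModelParams,
    ParamError,
    krw_to_usd,
    table1_params,
)

PERIPROC_WINDOW = 30  # days: deaths in this window with no model event


def _first_year_mask(events: pd.DataFrame) -> pd.Series:
    return (events["event_day"] >= 0) & (events["event_day"] < 365)


def periprocedural_deaths(patients: pd.DataFrame, events: pd.DataFrame) -> set:
    """Ablation-arm patients dying within 30 days with no model event.

    These deaths belong to the periprocedural decision tree, not to the
    first Markov year, so they are removed from the first-year denominator.
    """
    abl = patients[patients["arm"] == "ablation"]
    death_day = pd.to_numeric(abl["death_day"], errors="coerce")
    early_dead = set(abl.loc[death_day.notna() & (death_day <= PERIPROC_WINDOW), "patient_id"])
    eventful = set(events.loc[events["event_type"].isin(EVENT_TYPES), "patient_id"])
    return early_dead - eventful


def estimate_first_year_probs(
    events: pd.DataFrame, arm_members: pd.DataFrame, arm: str
) -> dict[str, CountProb]:
    """Per-type first-year event probability for one arm."""
    if arm not in ARMS:
        raise ParamError(f"unknown arm {arm!r}")
    if len(arm_members) == 0:
        raise ParamError("arm membership table is empty")
    denominator = len(arm_members)
    if arm == "ablation":
        denominator -= len(periprocedural_deaths(arm_members, events))
    member_ids = set(arm_members["patient_id"])
    sub = events[
        events["patient_id"].isin(member_ids)
        & events["event_type"].isin(EVENT_TYPES)
        & _first_year_mask(events)
    ]
    counts = sub.groupby("event_type")["patient_id"].nunique()
    return {
        ev: CountProb(int(counts.get(ev, 0)), denominator) for ev in EVENT_TYPES
    }


def estimate_mortality(
    events: pd.DataFrame, arm_members: pd.DataFrame, arm: str
) -> CountProb:
    """First-year all-cause mortality, ablation arm net of periprocedural deaths."""
    if len(arm_members) == 0:
        raise ParamError("arm membership table is empty")
    denominator = len(arm_members)
    death_day = pd.to_numeric(arm_members["death_day"], errors="coerce")
    deaths = int((death_day.notna() & (death_day < 365)).sum())
    if arm == "ablation":
        peri = periprocedural_deaths(arm_members, events)
        denominator -= len(peri)
        deaths -= len(peri)
    return CountProb(deaths, denominator)


def estimate_fatality(events: pd.DataFrame) -> tuple[dict[str, CountProb], CountProb]:
    """Case fatality per event type (pooled over arms) and overall.

    Types with zero observed events are absent from the returned map.
    """
    sub = events[_first_year_mask(events) | (events["event_day"] == 0)]
    out: dict[str, CountProb] = {}
    total_fatal = total_events = 0
    for ev, grp in sub.groupby("event_type"):
        n, k = len(grp), int(grp["fatal"].sum())
        out[ev] = CountProb(k, n)
        total_fatal += k
        total_events += n
    overall = CountProb(total_fatal, max(total_events, 1))
    return out, overall


def estimate_costs(
    events: pd.DataFrame,
    arm_members: pd.DataFrame,
    currency: str = "USD",
    krw_per_usd: float = 1298.7,
) -> pd.DataFrame:
    """Mean annual cost (and SE) per event type among one arm's patients.

    ``currency="KRW"`` converts inputs to US dollars at the configured
    rate. Event types with no events are absent (callers should flag them).
    """
    if currency not in ("USD", "KRW"):
        raise ParamError(f"unknown currency {currency!r}")
    if (events["cost"] < 0).any():
        raise ParamError("negative cost in input events")
    member_ids = set(arm_members["patient_id"])
    sub = events[events["patient_id"].isin(member_ids)].copy()
    if currency == "KRW":
        sub["cost"] = sub["cost"].map(lambda c: krw_to_usd(c, krw_per_usd))
    rows = []
    for ev, grp in sub.groupby("event_type"):
        rows.append(
            {
                "event_type": ev,
                "n_events": len(grp),
                "mean_cost": grp["cost"].mean(),
                "se_cost": grp["cost"].std(ddof=1) / np.sqrt(len(grp))
                if len(grp) > 1
                else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["event_type", "n_events", "mean_cost", "se_cost"])


def compare_arm_event_rates(params: ModelParams) -> pd.DataFrame:
    """Pearson chi-square (no continuity correction) per event type."""
    rows = []
    comparisons = [(ev, ev) for ev in EVENT_TYPES] + [("all_cause_mortality", None)]
    for label, ev in comparisons:
        cps = {}
        for arm in ARMS:
            cp = params.event_probs[arm][ev] if ev else params.mortality[arm]
            if cp.denominator == 0:
                raise ParamError(f"zero denominator for {arm}/{label}")
            cps[arm] = cp
        table = np.array(
            [
                [cps[arm].numerator, cps[arm].denominator - cps[arm].numerator]
                for arm in ARMS
            ]
        )
        if table[:, 0].sum() == 0 or (table[:, 1] == table.sum(1)).all():
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"event_type": label, "chi2": float(chi2), "p_value": float(p)})
    return pd.DataFrame(rows)


def estimate_params(
    ablation_arm: pd.DataFrame,
    aad_arm: pd.DataFrame,
    events: pd.DataFrame,
    base: ModelParams | None = None,
) -> ModelParams:
    """Assemble a full parameter set from patient-level records.

    Estimates probabilities, mortality and fatality from the records;
    utilities, procedure/maintenance costs, run settings and anything else
    the schema cannot carry are taken from ``base`` (packaged defaults if
    omitted).
    """
    if base is None:
        base = table1_params()
    members = {"ablation": ablation_arm, "aads": aad_arm}
    event_probs = {
        arm: estimate_first_year_probs(events, members[arm], arm) for arm in ARMS
    }
    mortality = {arm: estimate_mortality(events, members[arm], arm) for arm in ARMS}
    fatality, _ = estimate_fatality(events)
    fat = dict(base.fatality)
    fat.update({ev: cp for ev, cp in fatality.items() if ev in fat})

    event_costs = {}
    for arm in ARMS:
        table = estimate_costs(events, members[arm]).set_index("event_type")
        event_costs[arm] = {
            ev: float(table.loc[ev, "mean_cost"])
            if ev in table.index
            else base.event_costs[arm][ev]
            for ev in EVENT_TYPES
        }

    # periprocedural tree counts from the ablation arm's day-0 records
    n_abl = len(ablation_arm)
    abl_ids = set(ablation_arm["patient_id"])
    proc = events[events["patient_id"].isin(abl_ids)]
    n_stroke = proc.loc[proc["event_type"] == "PROC_STROKE_TIA", "patient_id"].nunique()
    n_tamp = proc.loc[proc["event_type"] == "TAMPONADE", "patient_id"].nunique()
    n_death = len(periprocedural_deaths(ablation_arm, events))

    return ModelParams(
        event_probs=event_probs,
        mortality=mortality,
        proc_major_complication=CountProb(n_stroke + n_tamp + n_death, max(n_abl, 1)),
        proc_stroke=CountProb(n_stroke, max(n_abl, 1)),
        proc_tamponade=CountProb(n_tamp, max(n_abl, 1)),
        proc_death=CountProb(n_death, max(n_abl, 1)),
        fatality=fat,
        utilities=dict(base.utilities),
        procedure_costs=dict(base.procedure_costs),
        event_costs=event_costs,
        event_free_cost=dict(base.event_free_cost),
        post_proc_stroke_annual_cost=base.post_proc_stroke_annual_cost,
        discount_rate=base.discount_rate,
        horizon=base.horizon,
        wtp=base.wtp,
        krw_per_usd=base.krw_per_usd,
        post_event_cost=base.post_event_cost,
    )
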