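"""Synthetic patient-level claims data with the structure the model assumes.

The national claims extract behind the default parameters is not publicly
accessible, so this module generates cohorts with the same statistical
skeleton: per-arm first-year event probabilities, event-type-specific case
fatality, annual all-cause mortality, right-skewed per-event annual costs,
and antiarrhythmic-drug (AAD) dispensing histories dense enough to compute
a medication possession ratio (MPR). It exists so the cohort-selection and
parameter-estimation stages are exercisable end to end; it makes no claim
to diagnostic-code or billing realism.

Day 0 is the AF diagnosis (index date). First-year events are placed
uniformly over days 0-364. A fatal event sets the patient's death day to
the event day; non-event deaths are drawn at the configured annual
mortality minus the expected event-attributable death mass (floored at 0).
A patient can experience several distinct event types in year one (the
per-type risks are marginal and drawn independently).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import EVENT_TYPES, ModelParams, ParamError, table1_params

#: Event types the generator can emit (model events + periprocedural ones).
ALL_EVENT_TYPES = EVENT_TYPES + ("PROC_STROKE_TIA", "TAMPONADE")

AAD_CLASSES = ("amiodarone", "flecainide", "propafenone", "sotalol", "dronedarone")

PATIENT_COLUMNS = ["patient_id", "age_at_index", "sex", "arm", "index_date", "death_day"]
EVENT_COLUMNS = ["patient_id", "event_type", "event_day", "fatal", "cost"]
DISPENSING_COLUMNS = ["patient_id", "drug_class", "start_day", "days_supplied"]


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    Defaults reproduce the claims-cohort world of the packaged parameter
    set: 2,131 ablation and 8,048 AAD patients, mean age 62 (SD 9,
    truncated to 18-74), 57% male, Table-style event/fatality/mortality
    probabilities and mean annual event costs with a gamma cost model
    (coefficient of variation 0.5), and AAD adherence spread across the
    0.80 MPR threshold.
    """

    n_patients: int = 10_179
    arm_fractions: dict[str, float] = field(
        default_factory=lambda: {"ablation": 2131 / 10179, "aads": 8048 / 10179}
    )
    age_mean: float = 62.0
    age_sd: float = 9.0
    age_bounds: tuple[float, float] = (18.0, 74.0)
    male_fraction: float = 0.57
    first_year_event_probs: dict[str, dict[str, float]] | None = None
    fatality_probs: dict[str, float] | None = None
    annual_mortality: dict[str, float] | None = None
    cost_means: dict[str, dict[str, float]] | None = None
    cost_cv: float = 0.5
    adherence_alpha: float = 8.5  # Beta adherence: mean 0.85, mass both sides of 0.80
    adherence_beta: float = 1.5
    days_per_fill: int = 30
    prior_event_prob: float = 0.0  # history events in the lookback year, for cascade tests
    seed: int = 0

    def __post_init__(self) -> None:
        base = table1_params()
        if self.first_year_event_probs is None:
            self.first_year_event_probs = {
                arm: {ev: base.event_probs[arm][ev].prob for ev in EVENT_TYPES}
                for arm in ("ablation", "aads")
            }
            self.first_year_event_probs["ablation"]["PROC_STROKE_TIA"] = base.proc_stroke.prob
            self.first_year_event_probs["ablation"]["TAMPONADE"] = base.proc_tamponade.prob
        if self.fatality_probs is None:
            self.fatality_probs = {
                ev: base.fatality[ev].prob for ev in EVENT_TYPES + ("PROC_STROKE_TIA",)
            }
            self.fatality_probs["TAMPONADE"] = 0.0
        if self.annual_mortality is None:
            self.annual_mortality = {
                arm: base.mortality[arm].prob for arm in ("ablation", "aads")
            }
        if self.cost_means is None:
            self.cost_means = {
                arm: {ev: base.event_costs[arm][ev] for ev in EVENT_TYPES}
                for arm in ("ablation", "aads")
            }
            self.cost_means["ablation"]["PROC_STROKE_TIA"] = base.procedure_costs[
                "PROC_STROKE_TIA"
            ]
            self.cost_means["ablation"]["TAMPONADE"] = base.procedure_costs["TAMPONADE"]
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ParamError("n_patients must be >= 1")
        if abs(sum(self.arm_fractions.values()) - 1.0) > 1e-9:
            raise ParamError("arm_fractions must sum to 1")
        for ev, p in self.fatality_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ParamError(f"fatality_probs[{ev}]={p} outside [0, 1]")
        for arm, m in self.annual_mortality.items():
            if not 0.0 <= m <= 1.0:
                raise ParamError(f"annual_mortality[{arm}]={m} outside [0, 1]")
        for arm, probs in self.first_year_event_probs.items():
            for ev, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ParamError(f"first_year_event_probs[{arm}][{ev}]={p} outside [0, 1]")
            model_mass = sum(probs.get(ev, 0.0) for ev in EVENT_TYPES)
            if model_mass + self.annual_mortality.get(arm, 0.0) > 1.0 + 1e-9:
                raise ParamError(
                    f"arm {arm!r}: event probabilities plus mortality exceed 1"
                )
        for arm, tbl in self.cost_means.items():
            for ev, c in tbl.items():
                if c <= 0:
                    raise ParamError(f"cost_means[{arm}][{ev}]={c} must be > 0")
        if self.cost_cv <= 0:
            raise ParamError("cost_cv must be > 0")
        if not 0.0 <= self.prior_event_prob <= 1.0:
            raise ParamError("prior_event_prob outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, events, dispensings) tables.

    Deterministic given ``config.seed``. Event costs are gamma draws with
    the configured mean and coefficient of variation. Periprocedural
    events occur on day 0 in the ablation arm.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    arms = sorted(config.arm_fractions)
    arm_p = np.array([config.arm_fractions[a] for a in arms])
    arm = rng.choice(arms, size=n, p=arm_p)
    age = np.round(
        _truncated_normal(
            rng, config.age_mean, config.age_sd, *config.age_bounds, size=n
        )
    ).astype(int)
    sex = (rng.random(n) < config.male_fraction).astype(int)  # 1 = male
    pid = np.array([f"P{i:07d}" for i in range(n)])

    shape = 1.0 / config.cost_cv**2
    death_day = np.full(n, -1, dtype=int)  # -1 = alive
    events: list[tuple] = []

    for arm_name in arms:
        idx = np.flatnonzero(arm == arm_name)
        probs = config.first_year_event_probs.get(arm_name, {})
        cost_means = config.cost_means.get(arm_name, {})
        ev_death_mass = sum(
            probs.get(ev, 0.0) * config.fatality_probs.get(ev, 0.0)
            for ev in EVENT_TYPES
        )
        for ev in ALL_EVENT_TYPES:
            p = probs.get(ev, 0.0)
            if p == 0.0:
                continue
            hit = idx[rng.random(idx.size) < p]
            if hit.size == 0:
                continue
            periprocedural = ev in ("PROC_STROKE_TIA", "TAMPONADE")
            day = (
                np.zeros(hit.size, dtype=int)
                if periprocedural
                else rng.integers(0, 365, hit.size)
            )
            fatal = rng.random(hit.size) < config.fatality_probs.get(ev, 0.0)
            cost = rng.gamma(shape, cost_means.get(ev, 1.0) / shape, hit.size)
            for j, pat in enumerate(hit):
                events.append((pat, ev, int(day[j]), bool(fatal[j]), float(cost[j])))
        # history events in the lookback window, for selection-cascade tests
        if config.prior_event_prob > 0:
            hit = idx[rng.random(idx.size) < config.prior_event_prob]
            for pat in hit:
                ev = EVENT_TYPES[rng.integers(0, len(EVENT_TYPES))]
                day = -int(rng.integers(1, 366))
                cost = float(rng.gamma(shape, cost_means.get(ev, 1.0) / shape))
                events.append((pat, ev, day, False, cost))
        # non-event deaths: annual mortality minus event-attributable mass
        p_other = max(0.0, config.annual_mortality.get(arm_name, 0.0) - ev_death_mass)
        if p_other > 0:
            dying = idx[rng.random(idx.size) < p_other]
            death_day[dying] = rng.integers(0, 365, dying.size)

    # fatal events: death on the event day; censor anything afterwards
    ev_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    if len(ev_df):
        ev_df["patient_id"] = ev_df["patient_id"].astype(int)  # positional for now
        fatal_first = (
            ev_df[ev_df["fatal"] & (ev_df["event_day"] >= 0)]
            .groupby("patient_id")["event_day"]
            .min()
        )
        for pat, day in fatal_first.items():
            death_day[pat] = day if death_day[pat] < 0 else min(death_day[pat], int(day))
        # drop post-mortem rows; an event is fatal only if it falls on the death day
        dd = pd.Series(
            death_day[ev_df["patient_id"].to_numpy(dtype=int)], index=ev_df.index
        )
        alive_mask = (dd < 0) | (ev_df["event_day"] <= dd)
        ev_df = ev_df[alive_mask].copy()
        dd = dd[alive_mask]
        ev_df["fatal"] = ev_df["fatal"] & (ev_df["event_day"] == dd)

    # AAD dispensings: refill cadence stretched by a per-patient adherence level
    disp: list[tuple] = []
    aad_idx = np.flatnonzero(arm == "aads")
    adherence = rng.beta(config.adherence_alpha, config.adherence_beta, aad_idx.size)
    drug = rng.choice(AAD_CLASSES, aad_idx.size)
    fill = config.days_per_fill
    for k, pat in enumerate(aad_idx):
        end = 365 if death_day[pat] < 0 else min(365, death_day[pat] + 1)
        day = 0
        step = fill / max(adherence[k], 1e-3)
        while day < end:
            disp.append((pat, drug[k], int(day), fill))
            day += step
    disp_df = pd.DataFrame(disp, columns=DISPENSING_COLUMNS)

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "age_at_index": age,
            "sex": sex,
            "arm": arm,
            "index_date": 0,
            "death_day": np.where(death_day < 0, pd.NA, death_day),
        }
    )
    if len(ev_df):
        ev_df["patient_id"] = pid[ev_df["patient_id"].to_numpy(dtype=int)]
    if len(disp_df):
        disp_df["patient_id"] = pid[disp_df["patient_id"].to_numpy(dtype=int)]
    return patients, ev_df.reset_index(drop=True), disp_df


def write_cohort(
    outdir: str | Path,
    patients: pd.DataFrame,
    events: pd.DataFrame,
    dispensings: pd.DataFrame,
    config: CohortConfig | None = None,
) -> dict[str, Path]:
    """Write the three cohort CSVs plus a JSON sidecar echoing the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": outdir / "patients.csv",
        "events": outdir / "events.csv",
        "dispensings": outdir / "dispensings.csv",
    }
    patients.to_csv(paths["patients"], index=False)
    events.to_csv(paths["events"], index=False)
    dispensings.to_csv(paths["dispensings"], index=False)
    if config is not None:
        sidecar = outdir / "cohort_config.json"
        sidecar.write_text(json.dumps(config.to_dict(), indent=2, default=str))
        paths["config"] = sidecar
    return paths


def read_cohort(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read cohort CSVs written by :func:`write_cohort`."""
    indir = Path(indir)
    patients = pd.read_csv(indir / "patients.csv", dtype={"patient_id": str})
    events = pd.read_csv(indir / "events.csv", dtype={"patient_id": str})
    dispensings = pd.read_csv(indir / "dispensings.csv", dtype={"patient_id": str})
    return patients, events, dispensings
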