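"""Inclusion/exclusion cascade for patient-level rhythm-control cohorts.

Reproduces the study-population logic on claims-style tables: adults under
75 at the index AF diagnosis, no model health event in the lookback year
before index, no death or health event within six weeks after index; the
ablation arm is every remaining patient with the ablation marker, and the
drug arm is every remaining non-ablation patient with at least one
antiarrhythmic-drug dispensing and a medication possession ratio (MPR) of
at least 80% over the first year. An MPR of exactly 0.80 is included (the
exclusion rule is "less than 80%").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .params import EVENT_TYPES, ParamError

KNOWN_ARMS = {"ablation", "aads"}


@dataclass(frozen=True)
class SelectionConfig:
    age_min: int = 18
    age_max_exclusive: int = 75
    prior_event_lookback: int = 365  # days before index
    early_event_window: int = 42  # days; six weeks, half-open [0, 42)
    mpr_threshold: float = 0.80
    mpr_window: int = 365  # days

    def __post_init__(self) -> None:
        if not 0.0 < self.mpr_threshold <= 1.0:
            raise ParamError("mpr_threshold must be in (0, 1]")
        for name in ("prior_event_lookback", "early_event_window", "mpr_window"):
            if getattr(self, name) <= 0:
                raise ParamError(f"{name} must be > 0")


@dataclass
class SelectionReport:
    """Patient counts at each cascade step."""

    identified: int
    after_age_filter: int
    after_prior_event_filter: int
    after_early_event_filter: int
    ablation_n: int
    aad_candidates: int
    after_rhythm_therapy_filter: int
    after_mpr_filter: int

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compute_mpr(dispensings: pd.DataFrame, window: int = 365) -> float:
    """Medication possession ratio: distinct covered days / window.

    Supply intervals are unioned day-wise (overlapping dispensings do not
    double-count) and clipped to ``[0, window)``; the ratio is capped at 1.
    An empty dispensing table yields 0.0.
    """
    if window <= 0:
        raise ParamError("MPR window must be > 0")
    if len(dispensings) == 0:
        return 0.0
    covered = np.zeros(window, dtype=bool)
    start = dispensings["start_day"].to_numpy(dtype=int)
    supply = dispensings["days_supplied"].to_numpy(dtype=int)
    if (supply < 1).any():
        raise ParamError("days_supplied must be >= 1")
    for s, d in zip(start, supply):
        lo, hi = max(s, 0), min(s + d, window)
        if hi > lo:
            covered[lo:hi] = True
    return min(covered.sum() / window, 1.0)


def _patients_with_event_in(events: pd.DataFrame, lo: int, hi: int) -> set:
    """Patient ids with any model event in the half-open day window [lo, hi)."""
    sub = events[
        events["event_type"].isin(EVENT_TYPES)
        & (events["event_day"] >= lo)
        & (events["event_day"] < hi)
    ]
    return set(sub["patient_id"])


def select_cohort(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    dispensings: pd.DataFrame,
    config: SelectionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SelectionReport]:
    """Apply the cascade; return (ablation arm, AAD arm, report)."""
    if config is None:
        config = SelectionConfig()
    unknown = set(patients["arm"].unique()) - KNOWN_ARMS
    if unknown:
        raise ParamError(f"unknown arm label(s): {sorted(unknown)}")

    identified = len(patients)
    kept = patients[
        (patients["age_at_index"] >= config.age_min)
        & (patients["age_at_index"] < config.age_max_exclusive)
    ]
    after_age = len(kept)

    prior = _patients_with_event_in(events, -config.prior_event_lookback, 0)
    kept = kept[~kept["patient_id"].isin(prior)]
    after_prior = len(kept)

    early = _patients_with_event_in(events, 0, config.early_event_window)
    death_day = pd.to_numeric(kept["death_day"], errors="coerce")
    early_death = death_day.notna() & (death_day < config.early_event_window)
    kept = kept[~kept["patient_id"].isin(early) & ~early_death]
    after_early = len(kept)

    ablation = kept[kept["arm"] == "ablation"]
    non_ablation = kept[kept["arm"] != "ablation"]
    aad_candidates = len(non_ablation)

    has_aad = set(dispensings["patient_id"]) if len(dispensings) else set()
    with_therapy = non_ablation[non_ablation["patient_id"].isin(has_aad)]
    after_therapy = len(with_therapy)

    if len(with_therapy):
        mpr = (
            dispensings[dispensings["patient_id"].isin(with_therapy["patient_id"])]
            .groupby("patient_id")
            .apply(lambda g: compute_mpr(g, config.mpr_window), include_groups=False)
        )
        adherent = set(mpr[mpr >= config.mpr_threshold].index)
        aad_arm = with_therapy[with_therapy["patient_id"].isin(adherent)]
    else:
        aad_arm = with_therapy
    report = SelectionReport(
        identified=identified,
        after_age_filter=after_age,
        after_prior_event_filter=after_prior,
        after_early_event_filter=after_early,
        ablation_n=len(ablation),
        aad_candidates=aad_candidates,
        after_rhythm_therapy_filter=after_therapy,
        after_mpr_filter=len(aad_arm),
    )
    return ablation.reset_index(drop=True), aad_arm.reset_index(drop=True), report
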