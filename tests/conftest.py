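import numpy as np
import pytest

import afibcea as af
from afibcea.params import CountProb, ModelParams, Utility

DEN = 100_000  # denominator used to encode exact probabilities as counts


def cp(p: float, den: int = DEN) -> CountProb:
    return CountProb(int(round(p * den)), den)


def make_params(
    probs_ablation=None,
    probs_aads=None,
    mort_ablation=0.0,
    mort_aads=0.0,
    fatality=None,
    utilities=None,
    costs_ablation=None,
    costs_aads=None,
    free_cost=(1016.8, 1221.5),
    proc=(0.0, 0.0, 0.0),  # stroke, tamponade, 30-day death probabilities
    proc_fatality=0.0,
    discount=0.045,
    horizon=20,
    post_event_cost="event",
) -> ModelParams:
    """Build a ModelParams with explicit numbers and quiet defaults."""
    zeros = {ev: 0.0 for ev in af.EVENT_TYPES}
    probs = {
        "ablation": {**zeros, **(probs_ablation or {})},
        "aads": {**zeros, **(probs_aads or {})},
    }
    fat = {**zeros, "PROC_STROKE_TIA": proc_fatality, **(fatality or {})}
    utils = {
        "EVENT_FREE": 0.95,
        "HF_HOSP": 0.73,
        "MI": 0.73,
        "ISCHEMIC_STROKE": 0.60,
        "ICH": 0.67,
        **(utilities or {}),
    }
    base_costs = {ev: 1000.0 for ev in af.EVENT_TYPES}
    return ModelParams(
        event_probs={arm: {ev: cp(v) for ev, v in tbl.items()} for arm, tbl in probs.items()},
        mortality={"ablation": cp(mort_ablation), "aads": cp(mort_aads)},
        proc_major_complication=cp(min(sum(proc), 1.0)),
        proc_stroke=cp(proc[0]),
        proc_tamponade=cp(proc[1]),
        proc_death=cp(proc[2]),
        fatality={ev: cp(v) for ev, v in fat.items()},
        utilities={k: Utility(v, max(v - 0.05, 0.0), min(v + 0.05, 1.0)) for k, v in utils.items()},
        procedure_costs={
            "no_complication": 1879.4,
            "PROC_STROKE_TIA": 6187.9,
            "TAMPONADE": 5189.8,
        },
        event_costs={
            "ablation": {**base_costs, **(costs_ablation or {})},
            "aads": {**base_costs, **(costs_aads or {})},
        },
        event_free_cost={"ablation": free_cost[0], "aads": free_cost[1]},
        post_proc_stroke_annual_cost=1774.8,
        discount_rate=discount,
        horizon=horizon,
        post_event_cost=post_event_cost,
    )


def random_params(rng: np.random.Generator) -> ModelParams:
    """A random but valid parameter set (used by oracle/property tests)."""
    probs, mort, costs = {}, {}, {}
    for arm in af.ARMS:
        raw = rng.dirichlet(np.ones(7))
        probs[arm] = {ev: 0.6 * raw[i] for i, ev in enumerate(af.EVENT_TYPES)}
        mort[arm] = min(0.6 * raw[5], 0.5)
        costs[arm] = {ev: float(rng.uniform(1000, 20000)) for ev in af.EVENT_TYPES}
    fat = {ev: float(rng.uniform(0, 0.4)) for ev in af.EVENT_TYPES}
    utils = {
        k: float(rng.uniform(0.3, 1.0))
        for k in ("EVENT_FREE", "HF_HOSP", "MI", "ISCHEMIC_STROKE", "ICH")
    }
    return make_params(
        probs_ablation=probs["ablation"],
        probs_aads=probs["aads"],
        mort_ablation=mort["ablation"],
        mort_aads=mort["aads"],
        fatality=fat,
        utilities=utils,
        costs_ablation=costs["ablation"],
        costs_aads=costs["aads"],
        proc=(float(rng.uniform(0, 0.1)), float(rng.uniform(0, 0.05)), float(rng.uniform(0, 0.01))),
        proc_fatality=float(rng.uniform(0, 0.3)),
    )


@pytest.fixture(scope="session")
def table1() -> ModelParams:
    return af.table1_params()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across selection/estimation tests."""
    cfg = af.CohortConfig(n_patients=6000, seed=7)
    patients, events, dispensings = af.generate_cohort(cfg)
    return cfg, patients, events, dispensings
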