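"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way DSA
-----------
Each parameter is swung to a low and a high value with everything else at
base case, the full two-arm model is re-run, and the ICER spread is
reported in descending order (a tornado table). Default ranges follow
common practice for count/CI-sourced parameters: utilities use their
printed 95% CI; costs use the 2.5-97.5 percentiles of the moment-matched
gamma (no cost CIs are printed); transition probabilities use +/- 10% of
the base value. The discount rate is swept separately over 0-7%.

PSA
---
Each replicate redraws every varied parameter from its assigned family
(normal for most transition probabilities, truncated to [0, 1]; beta for
mortality, case fatality and utilities; gamma for costs), runs both arms,
and records the incremental cost/effect pair. Hyperparameters are derived
from the raw counts (beta: events / non-events), the printed 95% CI
(utilities, by moment matching) or the mean with a configurable
coefficient of variation (costs, default 0.5). Replicates are summarised
as means, 2.5-97.5 percentile intervals, a cost-effectiveness
acceptability curve (CEAC) and cost-effectiveness-plane quadrant shares.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .economics import compute_icer
from .markov import run_markov, state_costs, state_utilities, transition_matrix, \
    run_periprocedural_tree, HealthState, N_STATES
from .params import (
    ARMS,
    EVENT_TYPES,
    FixedProb,
    ModelParams,
    ParamError,
    Utility,
)

# --------------------------------------------------------------------------
# parameter addressing


def _clamp(value: float, lo: float, hi: float, pid: str) -> float:
    if value < lo or value > hi:
        warnings.warn(f"{pid}: value {value} clamped to [{lo}, {hi}]", stacklevel=3)
        return min(max(value, lo), hi)
    return value


def get_param(params: ModelParams, pid: str) -> float:
    """Read a scalar parameter by its id (see :func:`set_params`)."""
    try:
        return _get_param(params, pid)
    except KeyError as exc:
        raise ParamError(f"unknown parameter id {pid!r}: {exc}") from exc


def _get_param(params: ModelParams, pid: str) -> float:
    kind, _, rest = pid.partition(":")
    if kind == "utility":
        return params.utilities[rest].value
    if kind == "cost":
        sub, _, tail = rest.partition(":")
        if sub == "event":
            arm, _, ev = tail.partition(":")
            return params.event_costs[arm][ev]
        if sub == "event_free":
            return params.event_free_cost[tail]
        if sub == "procedure":
            return params.procedure_costs[tail]
    if kind == "prob":
        sub, _, tail = rest.partition(":")
        if sub == "event":
            arm, _, ev = tail.partition(":")
            return params.event_probs[arm][ev].prob
        if sub == "mortality":
            return params.mortality[tail].prob
        if sub == "fatality":
            return params.fatality[tail].prob
        if sub == "proc":
            return {
                "stroke": params.proc_stroke,
                "tamponade": params.proc_tamponade,
                "death": params.proc_death,
            }[tail].prob
    raise ParamError(f"unknown parameter id {pid!r}")


def set_params(params: ModelParams, values: dict[str, float]) -> ModelParams:
    """Return a copy of ``params`` with the given parameter ids overridden.

    Probabilities and utilities are clamped to their support with a
    warning; costs are clamped at zero.
    """
    p = copy.copy(params)
    p.event_probs = {arm: dict(tbl) for arm, tbl in params.event_probs.items()}
    p.event_costs = {arm: dict(tbl) for arm, tbl in params.event_costs.items()}
    p.mortality = dict(params.mortality)
    p.fatality = dict(params.fatality)
    p.utilities = dict(params.utilities)
    p.procedure_costs = dict(params.procedure_costs)
    p.event_free_cost = dict(params.event_free_cost)

    for pid, value in values.items():
        get_param(params, pid)  # raises for unknown ids
        kind, _, rest = pid.partition(":")
        if kind == "utility":
            v = _clamp(value, 0.0, 1.0, pid)
            p.utilities[rest] = Utility(v, v, v)
        elif kind == "cost":
            v = _clamp(value, 0.0, np.inf, pid)
            sub, _, tail = rest.partition(":")
            if sub == "event":
                arm, _, ev = tail.partition(":")
                p.event_costs[arm][ev] = v
            elif sub == "event_free":
                p.event_free_cost[tail] = v
            else:
                p.procedure_costs[tail] = v
        else:  # prob
            v = _clamp(value, 0.0, 1.0, pid)
            sub, _, tail = rest.partition(":")
            if sub == "event":
                arm, _, ev = tail.partition(":")
                p.event_probs[arm][ev] = FixedProb(v)
            elif sub == "mortality":
                p.mortality[tail] = FixedProb(v)
            elif sub == "fatality":
                p.fatality[tail] = FixedProb(v)
            elif tail == "stroke":
                p.proc_stroke = FixedProb(v)
            elif tail == "tamponade":
                p.proc_tamponade = FixedProb(v)
            else:
                p.proc_death = FixedProb(v)
    p.validate()
    return p


def _iter_prob_ids(params: ModelParams):
    for arm in ARMS:
        for ev in EVENT_TYPES:
            yield f"prob:event:{arm}:{ev}"
        yield f"prob:mortality:{arm}"
    for ev in EVENT_TYPES + ("PROC_STROKE_TIA",):
        yield f"prob:fatality:{ev}"
    yield from ("prob:proc:stroke", "prob:proc:tamponade", "prob:proc:death")


def _iter_cost_ids(params: ModelParams):
    for arm in ARMS:
        for ev in EVENT_TYPES:
            yield f"cost:event:{arm}:{ev}"
        yield f"cost:event_free:{arm}"
    for key in params.procedure_costs:
        yield f"cost:procedure:{key}"


def _iter_utility_ids(params: ModelParams):
    for key in params.utilities:
        yield f"utility:{key}"


# --------------------------------------------------------------------------
# fast two-arm evaluation (no trace DataFrame)


def _arm_totals(arm: str, params: ModelParams) -> tuple[float, float]:
    """Discounted (cost, QALY) totals; lean path used by DSA/PSA."""
    if arm == "ablation":
        dist, upfront = run_periprocedural_tree(params)
    else:
        dist = np.zeros(N_STATES)
        dist[HealthState.EVENT_FREE_AF] = 1.0
        upfront = 0.0
    T = transition_matrix(params, arm)
    costs = state_costs(params, arm)
    utils = state_utilities(params)
    df = 1.0 / (1.0 + params.discount_rate)
    w = df ** np.arange(1, params.horizon + 1)
    total_cost, total_qaly = upfront, 0.0
    for t in range(params.horizon):
        dist = dist @ T
        total_cost += w[t] * float(dist @ costs)
        total_qaly += w[t] * float(dist @ utils)
    return total_cost, total_qaly


def _two_arm_icer(params: ModelParams) -> float:
    ca, qa = _arm_totals("aads", params)
    cb, qb = _arm_totals("ablation", params)
    return (cb - ca) / (qb - qa)


# --------------------------------------------------------------------------
# one-way deterministic sensitivity


@dataclass(frozen=True)
class DSARange:
    parameter_id: str
    low_value: float
    high_value: float
    source: str  # CI95 | pm10pct | discount_sweep

    def __post_init__(self) -> None:
        if self.low_value > self.high_value:
            raise ParamError(f"{self.parameter_id}: low > high")


def default_dsa_ranges(params: ModelParams, cost_cv: float = 0.5) -> list[DSARange]:
    """CI-based ranges for utilities/costs, +/-10% for probabilities."""
    ranges: list[DSARange] = []
    for pid in _iter_utility_ids(params):
        u = params.utilities[pid.split(":", 1)[1]]
        ranges.append(DSARange(pid, u.ci_low, u.ci_high, "CI95"))
    shape = 1.0 / cost_cv**2
    for pid in _iter_cost_ids(params):
        mean = get_param(params, pid)
        lo, hi = stats.gamma.ppf([0.025, 0.975], a=shape, scale=mean / shape)
        ranges.append(DSARange(pid, float(lo), float(hi), "CI95"))
    for pid in _iter_prob_ids(params):
        base = get_param(params, pid)
        ranges.append(DSARange(pid, 0.9 * base, 1.1 * base, "pm10pct"))
    return ranges


def one_way_dsa(params: ModelParams, ranges: list[DSARange]) -> pd.DataFrame:
    """Tornado table: ICER at each range end, sorted by descending spread."""
    base_icer = _two_arm_icer(params)
    rows = []
    for rng in ranges:
        get_param(params, rng.parameter_id)  # validate id exists
        icer_lo = _two_arm_icer(set_params(params, {rng.parameter_id: rng.low_value}))
        icer_hi = _two_arm_icer(set_params(params, {rng.parameter_id: rng.high_value}))
        rows.append(
            {
                "parameter": rng.parameter_id,
                "source": rng.source,
                "low_value": rng.low_value,
                "high_value": rng.high_value,
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "spread": abs(icer_hi - icer_lo),
            }
        )
    table = pd.DataFrame(rows).sort_values("spread", ascending=False, ignore_index=True)
    table.attrs["base_icer"] = base_icer
    return table


def discount_sweep(
    params: ModelParams, rates: tuple[float, ...] = (0.0, 0.03, 0.07)
) -> dict[float, float]:
    """Re-run the base case at alternative discount rates; ICER per rate."""
    return {r: _two_arm_icer(params.replace(discount_rate=r)) for r in rates}


# --------------------------------------------------------------------------
# probabilistic sensitivity


@dataclass(frozen=True)
class PSADistribution:
    """Sampling distribution of one parameter in the PSA."""

    parameter_id: str
    family: str  # normal | beta | gamma
    hyperparameters: dict

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        h = self.hyperparameters
        try:
            if self.family == "normal":
                if h["sigma"] == 0.0:  # point mass
                    return np.full(size, h["mu"])
                # truncated to [0, 1]: these are probabilities
                a = (0.0 - h["mu"]) / h["sigma"]
                b = (1.0 - h["mu"]) / h["sigma"]
                return stats.truncnorm.rvs(
                    a, b, loc=h["mu"], scale=h["sigma"], size=size, random_state=rng
                )
            if self.family == "beta":
                return rng.beta(h["alpha"], h["beta"], size=size)
            if self.family == "gamma":
                return rng.gamma(h["shape"], h["scale"], size=size)
        except (KeyError, ValueError) as exc:
            raise ParamError(
                f"invalid hyperparameters for {self.parameter_id}: {exc}"
            ) from exc
        raise ParamError(f"{self.parameter_id}: unknown family {self.family!r}")


def _beta_from_counts(pid: str, num: int, den: int) -> PSADistribution:
    if num == 0 or num == den:  # degenerate: no sampling information either side
        return PSADistribution(pid, "normal", {"mu": num / den, "sigma": 0.0})
    return PSADistribution(pid, "beta", {"alpha": num, "beta": den - num})


def _beta_from_ci(pid: str, u: Utility) -> PSADistribution:
    mean = u.value
    sd = (u.ci_high - u.ci_low) / 3.92
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ParamError(f"{pid}: CI too wide for a beta fit")
    return PSADistribution(pid, "beta", {"alpha": mean * nu, "beta": (1.0 - mean) * nu})


def default_psa_distributions(
    params: ModelParams, cost_cv: float = 0.5
) -> list[PSADistribution]:
    """Distribution assignments: normal (truncated) for event and
    periprocedural probabilities, beta for mortality/fatality/utilities,
    gamma for costs. The annual post-periprocedural-stroke cost has no
    assigned distribution and stays fixed."""
    dists: list[PSADistribution] = []
    for arm in ARMS:
        for ev in EVENT_TYPES:
            cp = params.event_probs[arm][ev]
            dists.append(
                PSADistribution(
                    f"prob:event:{arm}:{ev}", "normal", {"mu": cp.prob, "sigma": cp.se}
                )
            )
        cp = params.mortality[arm]
        dists.append(_beta_from_counts(f"prob:mortality:{arm}", cp.numerator, cp.denominator))
    for ev in EVENT_TYPES + ("PROC_STROKE_TIA",):
        cp = params.fatality[ev]
        dists.append(_beta_from_counts(f"prob:fatality:{ev}", cp.numerator, cp.denominator))
    for pid, cp in (
        ("prob:proc:stroke", params.proc_stroke),
        ("prob:proc:tamponade", params.proc_tamponade),
        ("prob:proc:death", params.proc_death),
    ):
        dists.append(PSADistribution(pid, "normal", {"mu": cp.prob, "sigma": cp.se}))
    for key, u in params.utilities.items():
        dists.append(_beta_from_ci(f"utility:{key}", u))
    shape = 1.0 / cost_cv**2
    for pid in _iter_cost_ids(params):
        mean = get_param(params, pid)
        dists.append(
            PSADistribution(pid, "gamma", {"shape": shape, "scale": mean / shape})
        )
    return dists


@dataclass
class PSAOutput:
    replicates: pd.DataFrame  # cost_i, qaly_i, cost_c, qaly_c, delta_cost, delta_effect
    summary: dict
    ceac: dict[float, float]
    quadrants: dict[str, float]
    seed: int
    n_reps: int

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "quadrants": self.quadrants,
            "seed": self.seed,
            "n_reps": self.n_reps,
        }


def ceac_curve(replicates: pd.DataFrame, wtp_grid) -> dict[float, float]:
    """Probability the intervention is cost-effective at each WTP value.

    A replicate counts as cost-effective when its net monetary benefit
    ``wtp * dE - dC`` is positive.
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ParamError("WTP grid must be nonempty")
    if len(replicates) == 0:
        raise ParamError("no PSA replicates")
    de = replicates["delta_effect"].to_numpy()
    dc = replicates["delta_cost"].to_numpy()
    return {
        float(w): float(np.mean(w * de - dc > 0.0)) for w in wtp_grid
    }


def _quadrants(replicates: pd.DataFrame) -> dict[str, float]:
    de = replicates["delta_effect"].to_numpy()
    dc = replicates["delta_cost"].to_numpy()
    return {
        "NE": float(np.mean((de >= 0) & (dc >= 0))),
        "SE": float(np.mean((de >= 0) & (dc < 0))),
        "SW": float(np.mean((de < 0) & (dc < 0))),
        "NW": float(np.mean((de < 0) & (dc >= 0))),
    }


def _interval(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return float(lo), float(hi)


def run_psa(
    params: ModelParams,
    n_reps: int = 10_000,
    seed: int = 0,
    distributions: list[PSADistribution] | None = None,
    wtp_grid=None,
) -> PSAOutput:
    """Monte-Carlo parameter resampling of the full two-arm model."""
    if n_reps < 1:
        raise ParamError("n_reps must be >= 1")
    if distributions is None:
        distributions = default_psa_distributions(params)
    if wtp_grid is None:
        wtp_grid = np.arange(0, 100_001, 1000)
    rng = np.random.default_rng(seed)
    draws = {
        d.parameter_id: d.sample(rng, n_reps)
        for d in sorted(distributions, key=lambda d: d.parameter_id)
    }
    recs = np.empty((n_reps, 4))
    for i in range(n_reps):
        values = {pid: float(col[i]) for pid, col in draws.items()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # clamp warnings in the tails
            p_i = set_params(params, values)
        cb, qb = _arm_totals("ablation", p_i)
        ca, qa = _arm_totals("aads", p_i)
        recs[i] = (cb, qb, ca, qa)
    replicates = pd.DataFrame(
        recs, columns=["cost_i", "qaly_i", "cost_c", "qaly_c"]
    )
    replicates["delta_cost"] = replicates["cost_i"] - replicates["cost_c"]
    replicates["delta_effect"] = replicates["qaly_i"] - replicates["qaly_c"]

    de = replicates["delta_effect"].to_numpy()
    dc = replicates["delta_cost"].to_numpy()
    icers = np.divide(dc, de, out=np.full_like(dc, np.nan), where=de != 0)
    summary = {}
    for label, col in (
        ("intervention_cost", "cost_i"),
        ("intervention_qaly", "qaly_i"),
        ("comparator_cost", "cost_c"),
        ("comparator_qaly", "qaly_c"),
        ("delta_cost", "delta_cost"),
        ("delta_effect", "delta_effect"),
    ):
        x = replicates[col].to_numpy()
        lo, hi = _interval(x)
        summary[label] = {"mean": float(x.mean()), "ci": [lo, hi]}
    finite = icers[np.isfinite(icers)]
    lo, hi = _interval(finite)
    summary["icer"] = {"mean": float(finite.mean()), "ci": [lo, hi]}
    summary["icer_of_means"] = float(dc.mean() / de.mean()) if de.mean() != 0 else None

    return PSAOutput(
        replicates=replicates,
        summary=summary,
        ceac=ceac_curve(replicates, wtp_grid),
        quadrants=_quadrants(replicates),
        seed=seed,
        n_reps=n_reps,
    )
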