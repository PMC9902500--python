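"""Model parameters for the AF rhythm-control cost-effectiveness model.

The parameter set mirrors how health-economic models are usually published:
transition probabilities as raw event counts over denominators (so binomial
uncertainty is recoverable), per-state utilities with 95% confidence
intervals, per-event and per-year costs in US dollars, and run settings
(horizon, discount rate, willingness-to-pay threshold).

:func:`table1_params` returns the packaged defaults: first-year event
probabilities, case fatalities, annual mortality and costs estimated from a
Korean nationwide claims cohort (2,131 ablation and 8,048 drug-treated
patients with newly diagnosed non-valvular AF), with literature utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

#: Recurring health events modelled in the annual Markov cycle.
EVENT_TYPES = ("HF_HOSP", "MI", "ISCHEMIC_STROKE", "ICH", "GI_BLEED")

#: Events confined to the periprocedural decision tree (ablation arm).
PROC_EVENT_TYPES = ("PROC_STROKE_TIA", "TAMPONADE")

#: Treatment strategies compared.
ARMS = ("ablation", "aads")

#: Admissible values of the post-event cost structural switch.
POST_EVENT_COST_CHOICES = ("event", "event_free")


class ParamError(ValueError):
    """A model parameter violates its support or an internal constraint."""


@dataclass(frozen=True)
class CountProb:
    """A probability stored as ``numerator / denominator`` raw counts."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ParamError(f"denominator must be positive, got {self.denominator}")
        if not 0 <= self.numerator <= self.denominator:
            raise ParamError(
                f"numerator {self.numerator} outside [0, {self.denominator}]"
            )

    @property
    def prob(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Probability on the 0-100 scale, as printed in parameter tables."""
        return 100.0 * self.prob

    @property
    def se(self) -> float:
        """Binomial standard error of the proportion."""
        p = self.prob
        return math.sqrt(p * (1.0 - p) / self.denominator)


@dataclass(frozen=True)
class FixedProb:
    """Continuous probability stand-in for :class:`CountProb`.

    Used when a sensitivity analysis overrides a count-derived probability
    with an arbitrary value in [0, 1]; exposes the same read interface.
    """

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ParamError(f"probability {self.p} outside [0, 1]")

    @property
    def prob(self) -> float:
        return self.p

    @property
    def percent(self) -> float:
        return 100.0 * self.p

    @property
    def se(self) -> float:
        return 0.0


@dataclass(frozen=True)
class Utility:
    """A health-state preference weight with its 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ParamError(f"utility {self.value} outside [0, 1]")
        if not self.ci_low <= self.value <= self.ci_high:
            raise ParamError(
                f"utility CI ({self.ci_low}, {self.ci_high}) does not bracket {self.value}"
            )


def krw_to_usd(amount_krw: float, krw_per_usd: float = 1298.7) -> float:
    """Convert Korean won to US dollars at the model's 2019 exchange rate."""
    if krw_per_usd <= 0:
        raise ParamError("exchange rate must be positive")
    return amount_krw / krw_per_usd


@dataclass
class ModelParams:
    """Complete parameter set consumed by the Markov engine and analyses."""

    event_probs: dict[str, dict[str, CountProb]]
    mortality: dict[str, CountProb]
    proc_major_complication: CountProb
    proc_stroke: CountProb
    proc_tamponade: CountProb
    proc_death: CountProb
    fatality: dict[str, CountProb]
    utilities: dict[str, Utility]
    procedure_costs: dict[str, float]
    event_costs: dict[str, dict[str, float]]
    event_free_cost: dict[str, float]
    post_proc_stroke_annual_cost: float
    discount_rate: float = 0.045
    horizon: int = 20
    wtp: float = 32000.0
    krw_per_usd: float = 1298.7
    post_event_cost: str = "event"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for arm in ARMS:
            if arm not in self.event_probs:
                raise ParamError(f"missing event probabilities for arm {arm!r}")
            for ev in EVENT_TYPES:
                if ev not in self.event_probs[arm]:
                    raise ParamError(f"missing event probability {arm}/{ev}")
                if ev not in self.event_costs.get(arm, {}):
                    raise ParamError(f"missing event cost {arm}/{ev}")
            if arm not in self.mortality:
                raise ParamError(f"missing mortality for arm {arm!r}")
            if self.event_free_cost.get(arm, -1.0) < 0:
                raise ParamError(f"missing or negative event-free cost for {arm!r}")
            total = sum(self.event_probs[arm][ev].prob for ev in EVENT_TYPES)
            total += self.mortality[arm].prob
            if total > 1.0 + 1e-12:
                raise ParamError(
                    f"arm {arm!r}: event probabilities plus mortality sum to {total:.4f} > 1"
                )
        for ev in EVENT_TYPES + ("PROC_STROKE_TIA",):
            if ev not in self.fatality:
                raise ParamError(f"missing fatality for {ev}")
        for state in ("EVENT_FREE",) + EVENT_TYPES[:4]:
            if state not in self.utilities:
                raise ParamError(f"missing utility for {state}")
        tree = self.proc_stroke.prob + self.proc_tamponade.prob + self.proc_death.prob
        if tree > 1.0 + 1e-12:
            raise ParamError(f"periprocedural branch probabilities sum to {tree:.4f} > 1")
        for label, cost in self.iter_costs():
            if cost < 0:
                raise ParamError(f"negative cost for {label}: {cost}")
        if self.discount_rate < 0:
            raise ParamError("discount rate must be >= 0")
        if self.horizon < 1:
            raise ParamError("horizon must be at least one cycle")
        if self.post_event_cost not in POST_EVENT_COST_CHOICES:
            raise ParamError(
                f"post_event_cost must be one of {POST_EVENT_COST_CHOICES}, "
                f"got {self.post_event_cost!r}"
            )

    def iter_costs(self):
        for key, val in self.procedure_costs.items():
            yield f"procedure/{key}", val
        for arm, table in self.event_costs.items():
            for ev, val in table.items():
                yield f"{arm}/{ev}", val
        for arm, val in self.event_free_cost.items():
            yield f"{arm}/event_free", val
        yield "post_proc_stroke_annual", self.post_proc_stroke_annual_cost

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "event_probs": {
                arm: {ev: [cp.numerator, cp.denominator] for ev, cp in tbl.items()}
                for arm, tbl in self.event_probs.items()
            },
            "mortality": {
                arm: [cp.numerator, cp.denominator] for arm, cp in self.mortality.items()
            },
            "periprocedural": {
                "major_complication": [
                    self.proc_major_complication.numerator,
                    self.proc_major_complication.denominator,
                ],
                "PROC_STROKE_TIA": [self.proc_stroke.numerator, self.proc_stroke.denominator],
                "TAMPONADE": [self.proc_tamponade.numerator, self.proc_tamponade.denominator],
                "death_30d": [self.proc_death.numerator, self.proc_death.denominator],
            },
            "fatality": {
                ev: [cp.numerator, cp.denominator] for ev, cp in self.fatality.items()
            },
            "utilities": {
                st: [u.value, u.ci_low, u.ci_high] for st, u in self.utilities.items()
            },
            "procedure_costs": dict(self.procedure_costs),
            "event_costs": {arm: dict(tbl) for arm, tbl in self.event_costs.items()},
            "event_free_cost": dict(self.event_free_cost),
            "post_proc_stroke_annual_cost": self.post_proc_stroke_annual_cost,
            "discount_rate": self.discount_rate,
            "horizon": self.horizon,
            "wtp": self.wtp,
            "krw_per_usd": self.krw_per_usd,
            "post_event_cost": self.post_event_cost,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        cp = lambda pair: CountProb(int(pair[0]), int(pair[1]))
        peri = d["periprocedural"]
        return cls(
            event_probs={
                arm: {ev: cp(v) for ev, v in tbl.items()}
                for arm, tbl in d["event_probs"].items()
            },
            mortality={arm: cp(v) for arm, v in d["mortality"].items()},
            proc_major_complication=cp(peri["major_complication"]),
            proc_stroke=cp(peri["PROC_STROKE_TIA"]),
            proc_tamponade=cp(peri["TAMPONADE"]),
            proc_death=cp(peri["death_30d"]),
            fatality={ev: cp(v) for ev, v in d["fatality"].items()},
            utilities={st: Utility(*map(float, v)) for st, v in d["utilities"].items()},
            procedure_costs={k: float(v) for k, v in d["procedure_costs"].items()},
            event_costs={
                arm: {ev: float(v) for ev, v in tbl.items()}
                for arm, tbl in d["event_costs"].items()
            },
            event_free_cost={arm: float(v) for arm, v in d["event_free_cost"].items()},
            post_proc_stroke_annual_cost=float(d["post_proc_stroke_annual_cost"]),
            discount_rate=float(d.get("discount_rate", 0.045)),
            horizon=int(d.get("horizon", 20)),
            wtp=float(d.get("wtp", 32000.0)),
            krw_per_usd=float(d.get("krw_per_usd", 1298.7)),
            post_event_cost=str(d.get("post_event_cost", "event")),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with top-level fields replaced (used by DSA/PSA)."""
        d = {k: v for k, v in self.__dict__.items()}
        d.update(kwargs)
        return ModelParams(**d)


def load_params(path: str | Path) -> ModelParams:
    """Read a :class:`ModelParams` YAML document."""
    with open(path) as fh:
        return ModelParams.from_dict(yaml.safe_load(fh))


def table1_params() -> ModelParams:
    """The packaged default parameter set (claims-cohort estimates)."""
    text = resources.files("afibcea").joinpath("data/table1_params.yaml").read_text()
    return ModelParams.from_dict(yaml.safe_load(text))
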