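"""Incremental cost-effectiveness of one strategy against a comparator.

The incremental cost-effectiveness ratio (ICER) is the incremental cost per
incremental QALY, computed from unrounded arm totals (intervention minus
comparator). When the sign pattern makes the ratio meaningless the result
carries a dominance label instead: "dominant" (cheaper and at least as
effective), "dominated" (costlier and no more effective). The net monetary
benefit NMB = WTP x dE - dC is always defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .markov import ArmResult

#: ICER labels used when the ratio itself is not informative.
DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"
UNDEFINED = "undefined ICER"


@dataclass
class CEResult:
    delta_cost: float
    delta_effect: float
    icer: float | None
    label: str | None  # dominance label when icer is None or uninformative
    nmb: float
    wtp: float
    cost_effective: bool

    def verdict(self) -> str:
        if self.label is not None:
            return self.label
        return f"ICER {self.icer:,.2f} per QALY ({'<=':s} WTP)" if self.cost_effective \
            else f"ICER {self.icer:,.2f} per QALY (> WTP)"

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "label": self.label,
            "nmb": self.nmb,
            "wtp": self.wtp,
            "cost_effective": self.cost_effective,
        }


def compute_icer(
    intervention: ArmResult, comparator: ArmResult, wtp: float
) -> CEResult:
    """Compare two arm results at a willingness-to-pay threshold."""
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.total_qaly - comparator.total_qaly
    nmb = wtp * de - dc

    # cost_effective <=> NMB >= 0 in every quadrant; this agrees with
    # "dominant or ICER <= WTP" where the ICER is informative and extends
    # it correctly to the southwest quadrant (less costly, less effective).
    cost_effective = nmb >= 0.0
    icer: float | None = None
    label: str | None = None
    if dc == 0.0 and de == 0.0:
        label = EQUIVALENT
    elif de == 0.0:
        label = UNDEFINED
    elif dc <= 0.0 and de >= 0.0:
        label = DOMINANT
        icer = dc / de
    elif dc >= 0.0 and de <= 0.0:
        label = DOMINATED
        icer = dc / de
    else:
        icer = dc / de
    return CEResult(
        delta_cost=dc,
        delta_effect=de,
        icer=icer,
        label=label,
        nmb=nmb,
        wtp=wtp,
        cost_effective=cost_effective,
    )


def write_report(
    path: str | Path,
    intervention: ArmResult,
    comparator: ArmResult,
    ce: CEResult,
) -> None:
    """JSON report with arm totals, deltas, ICER/NMB and the verdict."""
    payload = {
        "intervention": intervention.summary(),
        "comparator": comparator.summary(),
        **ce.to_dict(),
        "verdict": ce.verdict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
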