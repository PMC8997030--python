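"""Incremental cost-effectiveness: ICER, dominance, net monetary benefit.

A negative ICER is sign-ambiguous (lower cost with higher effectiveness
and higher cost with lower effectiveness both divide to a negative
number), so headline output carries a dominance classification and the
raw ratio is reported alongside, never alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .markov import CEResult

__all__ = ["ICERResult", "icer", "net_monetary_benefit", "ProvenanceError"]


class ProvenanceError(ValueError):
    """Two results being compared came from different inputs."""


@dataclass(frozen=True)
class ICERResult:
    """Increments of the intervention over the comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None               # delta_cost / delta_qaly, None when dQ = 0
    classification: str              # dominant | dominated | tradeoff | tie
    cost_effective_at_wtp: bool
    wtp: float


def _classify(dc: float, dq: float) -> str:
    if dc == 0.0 and dq == 0.0:
        return "tie"
    if dc <= 0.0 and dq >= 0.0:
        return "dominant"
    if dc >= 0.0 and dq <= 0.0:
        return "dominated"
    return "tradeoff"


def icer(
    intervention: CEResult,
    comparator: CEResult,
    wtp: float,
    check_provenance: bool = True,
) -> ICERResult:
    """Incremental comparison of two strategy results at a WTP threshold.

    ``cost_effective_at_wtp`` is true when the intervention dominates, or
    when it trades higher cost for higher effectiveness at a ratio not
    exceeding ``wtp``.  Any QALY-losing intervention (dominated, or
    cost-saving at the price of effectiveness) is treated as inferior and
    never cost-effective; this keeps acceptance monotone in WTP.
    """
    if check_provenance and intervention.provenance != comparator.provenance:
        raise ProvenanceError(
            "results come from different parameter sets / life tables: "
            f"{intervention.provenance!r} vs {comparator.provenance!r}"
        )
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qaly - comparator.total_qaly
    ratio = dc / dq if dq != 0.0 else None
    cls = _classify(dc, dq)
    if cls == "dominant":
        ce = True
    elif cls == "tradeoff" and dq > 0:
        ce = ratio is not None and ratio <= wtp
    else:
        ce = False
    return ICERResult(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qaly=dq,
        icer=ratio,
        classification=cls,
        cost_effective_at_wtp=ce,
        wtp=wtp,
    )


def net_monetary_benefit(result: CEResult, wtp: float) -> float:
    """NMB = wtp * QALYs - cost; higher is better at the given WTP."""
    if wtp < 0 or not math.isfinite(wtp):
        raise ValueError(f"wtp must be a finite non-negative number, got {wtp!r}")
    return wtp * result.total_qaly - result.total_cost
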