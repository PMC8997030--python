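"""Screening decision tree: test outcome probabilities and Markov entry.

A single baseline screen classifies each cohort member as true positive,
false negative, true negative or false positive from the pre-test
probability and the arm's sensitivity/specificity.  True positives pass
through the transient "early detection" node within cycle 0: a fraction
``p_resect_early`` is resected (one-time resection cost) and the rest is
palliative from the outset.  Transient nodes never occupy a full cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet, StrategyDefinition, ValidationError
from .states import State, N_STATES

__all__ = ["InitialDistribution", "initial_distribution", "entry_states"]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class InitialDistribution:
    """Probabilities of the four screen outcomes plus the acute screen cost."""

    p_tp: float
    p_fn: float
    p_tn: float
    p_fp: float
    acute_cost: float

    def __post_init__(self) -> None:
        probs = (self.p_tp, self.p_fn, self.p_tn, self.p_fp)
        if min(probs) < 0.0:
            raise ValidationError(f"negative outcome probability in {probs}")
        if abs(sum(probs) - 1.0) > _SUM_TOL:
            raise ValidationError(f"outcome probabilities sum to {sum(probs)!r}, not 1")


def initial_distribution(
    strategy: StrategyDefinition, params: ParameterSet
) -> InitialDistribution:
    """TP/FN/TN/FP split of the screened cohort for one arm."""
    p = params.pretest_prob
    return InitialDistribution(
        p_tp=p * strategy.sensitivity,
        p_fn=p * (1.0 - strategy.sensitivity),
        p_tn=(1.0 - p) * strategy.specificity,
        p_fp=(1.0 - p) * (1.0 - strategy.specificity),
        acute_cost=strategy.acute_cost,
    )


def entry_states(
    dist: InitialDistribution, params: ParameterSet
) -> tuple[np.ndarray, float]:
    """Resolve the screen outcomes into cycle-0 Markov occupancy.

    Returns ``(occupancy, entry_cost)`` where ``occupancy`` is the cohort
    fraction per :class:`~lungscreen_cea.states.State` and ``entry_cost``
    is the total one-time cycle-0 cost per cohort member: the acute
    screen cost plus the resection cost of early-detected resected
    cancers.  No other state charges a one-time cost at entry.
    """
    occ = np.zeros(N_STATES)
    occ[State.AFTER_RESECTION_Y1] = dist.p_tp * params.p_resect_early
    occ[State.PALLIATIVE] = dist.p_tp * (1.0 - params.p_resect_early)
    occ[State.UNDETECTED_Y1] = dist.p_fn
    occ[State.NO_BC] = dist.p_tn
    occ[State.NO_BC_SUSPICIOUS] = dist.p_fp
    entry_cost = dist.acute_cost + dist.p_tp * params.p_resect_early * params.cost_resection
    return occ, entry_cost
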