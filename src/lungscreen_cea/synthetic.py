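"""Synthetic inputs and independent oracles.

Everything the test suite needs that is not a closed form comes from
here: parametric life tables (flat or exponential-in-age mortality),
random perturbations of the parameter set for invariant fuzzing, and a
per-patient Monte-Carlo microsimulation that walks individual patients
through the same decision tree and transition probabilities as the
cohort engine.  By the law of large numbers the microsimulation means
converge to the cohort totals, which makes it an independent oracle for
the deterministic engine (it shares the transition definitions but none
of the cohort/accrual algebra).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .decision_tree import initial_distribution
from .life_tables import LifeTable, LifeTableError
from .markov import (
    AccrualConvention,
    REFERENCE_CONVENTION,
    precompute_matrices,
)
from .parameters import ParameterSet, StrategyDefinition
from .states import N_STATES, State, UNDETECTED_STATES, state_costs, state_utilities

__all__ = [
    "SyntheticLifeTableSpec",
    "make_life_table",
    "MicrosimResult",
    "microsimulate",
    "perturb_parameters",
]


@dataclass(frozen=True)
class SyntheticLifeTableSpec:
    """Parametric mortality: flat ``q0`` or Gompertz-like q0*exp(g*(age-a0))."""

    age_start: int = 55
    age_end: int = 85
    model: str = "flat"     # "flat" | "exponential"
    q0: float = 0.01
    g: float = 0.0
    a0: int = 60

    def __post_init__(self) -> None:
        if self.model not in ("flat", "exponential"):
            raise ValueError(f"unknown mortality model {self.model!r}")
        if self.age_end < self.age_start:
            raise ValueError("age_end must be >= age_start")


def make_life_table(spec: SyntheticLifeTableSpec) -> LifeTable:
    """Evaluate a mortality specification into a validated :class:`LifeTable`."""
    ages = np.arange(spec.age_start, spec.age_end + 1)
    if spec.model == "flat":
        qx = np.full(ages.shape, float(spec.q0))
        label = f"synthetic:flat(q={spec.q0})"
    else:
        qx = spec.q0 * np.exp(spec.g * (ages - spec.a0))
        label = f"synthetic:exp(q0={spec.q0},g={spec.g},a0={spec.a0})"
    if np.any(qx > 1.0):
        first = int(ages[np.argmax(qx > 1.0)])
        raise LifeTableError(f"synthetic q exceeds 1 from age {first}")
    return LifeTable(ages=ages, qx=qx, source_label=label)


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo means and standard errors over simulated patients."""

    n_patients: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    seed: int


def microsimulate(
    strategy: StrategyDefinition,
    params: ParameterSet,
    lt: LifeTable,
    n_patients: int,
    seed: int,
    convention: AccrualConvention = REFERENCE_CONVENTION,
) -> MicrosimResult:
    """Stochastic per-patient walk through decision tree and Markov states.

    Uses the same transition matrices and accrual convention as the
    cohort engine but simulates each patient's path, so agreement with
    :func:`~lungscreen_cea.markov.run_cohort` within Monte-Carlo error is
    a genuine cross-check of the cohort algebra.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    H = params.horizon_cycles
    lt.require_coverage(params.start_age, H)
    rng = np.random.default_rng(seed)
    n = int(n_patients)

    # --- decision tree ---------------------------------------------------
    diseased = rng.random(n) < params.pretest_prob
    positive = np.where(
        diseased,
        rng.random(n) < strategy.sensitivity,
        rng.random(n) >= strategy.specificity,
    )
    state = np.full(n, int(State.NO_BC), dtype=np.int8)
    state[~diseased & positive] = State.NO_BC_SUSPICIOUS
    state[diseased & ~positive] = State.UNDETECTED_Y1
    tp = diseased & positive
    resected = tp & (rng.random(n) < params.p_resect_early)
    state[resected] = State.AFTER_RESECTION_Y1
    state[tp & ~resected] = State.PALLIATIVE

    cost = np.full(n, strategy.acute_cost)
    cost[resected] += params.cost_resection
    qaly = np.zeros(n)

    costs_v = state_costs(params)
    utils_v = state_utilities(params)
    if convention.cycle0_accrual:
        cost += costs_v[state]
        qaly += utils_v[state]

    # --- Markov walk ------------------------------------------------------
    mats = precompute_matrices(params, lt)
    cums = np.cumsum(mats, axis=2)
    r = params.discount_rate
    und = np.array([int(s) for s in UNDETECTED_STATES])
    for t in range(1, H + 1):
        prev = state
        u = rng.random(n)
        state = (u[:, None] > cums[t - 1][prev]).sum(axis=1).astype(np.int8)
        df = (1.0 + r) ** -t
        new_resection = np.isin(prev, und) & (state == State.AFTER_RESECTION_Y1)
        cost += np.where(new_resection, params.cost_resection * df, 0.0)
        if convention.half_cycle:
            occ_cost = 0.5 * (costs_v[prev] + costs_v[state])
            occ_util = 0.5 * (utils_v[prev] + utils_v[state])
        elif convention.basis == "start":
            occ_cost, occ_util = costs_v[prev], utils_v[prev]
        else:
            occ_cost, occ_util = costs_v[state], utils_v[state]
        cost += occ_cost * df
        qaly += occ_util * df

    def _se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    return MicrosimResult(
        n_patients=n,
        mean_cost=float(cost.mean()),
        se_cost=_se(cost),
        mean_qaly=float(qaly.mean()),
        se_qaly=_se(qaly),
        seed=seed,
    )


# fields that stay fixed under perturbation (structure, not magnitude)
_PERTURB_SKIP = {"start_age", "horizon_cycles", "detection_schedule", "wtp"}


def perturb_parameters(
    params: ParameterSet,
    relative_width: float,
    seed: int,
) -> ParameterSet:
    """Randomly scale every numeric field by U[1-w, 1+w], clamped to validity.

    The detection schedule's non-final entries are perturbed too; the
    final entry stays 1.0 so the undetected tunnel still drains.  Used to
    fuzz model invariants over a cloud of plausible parameter sets.
    """
    if not 0.0 <= relative_width < 1.0:
        raise ValueError("relative_width must be in [0, 1)")
    rng = np.random.default_rng(seed)
    w = relative_width
    changes: dict[str, object] = {}
    for f in dataclasses.fields(ParameterSet):
        if f.name in _PERTURB_SKIP:
            continue
        base = getattr(params, f.name)
        v = base * rng.uniform(1.0 - w, 1.0 + w)
        if f.name.startswith(("p_", "utility_", "pretest")):
            v = min(1.0, max(0.0, v))
        else:
            v = max(0.0, v)
        changes[f.name] = v
    sched = [
        min(1.0, max(0.0, d * rng.uniform(1.0 - w, 1.0 + w)))
        for d in params.detection_schedule[:-1]
    ] + [1.0]
    changes["detection_schedule"] = tuple(sched)
    return params.replace(**changes)
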