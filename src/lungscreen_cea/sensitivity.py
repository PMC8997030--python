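"""Deterministic and probabilistic sensitivity analysis.

Three instruments:

* :func:`one_way` / :func:`tornado` — re-run the comparison with one
  parameter at its low and high setting (all else at base case) and rank
  parameters by the spread of the resulting ICER.  Because a negative
  ICER signals dominance rather than a meaningful ratio, the signed ratio
  is recorded for plotting/ranking only and the dominance classification
  is kept alongside.
* :func:`threshold_ai_cost` / :func:`wtp_cost_table` — the per-screen AI
  surcharge enters only the cycle-0 cost of the AI arm, so the ICER is
  affine in it and the surcharge that attains a target ICER has the
  closed form ``c* = target * dE - dC0``; a bisection cross-check must
  agree to one cent.
* :func:`psa` — Monte-Carlo parameter uncertainty: beta distributions for
  probabilities and utilities, gamma for costs, moment-matched to the
  base value with a configurable relative standard error (default 10%).
  Per-iteration RNG streams are spawned from one seed, so results do not
  depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cea import ICERResult, icer
from .life_tables import LifeTable
from .markov import (
    AccrualConvention,
    REFERENCE_CONVENTION,
    accrue,
    precompute_matrices,
    run_cohort,
)
from .parameters import ParameterSet, StrategyDefinition, ValidationError

__all__ = [
    "ParameterPathError",
    "ThresholdError",
    "resolve_parameter",
    "apply_parameter",
    "TornadoEntry",
    "one_way",
    "default_dsa_ranges",
    "tornado",
    "threshold_ai_cost",
    "wtp_cost_table",
    "DistributionSpec",
    "default_psa_specs",
    "PSAResult",
    "psa",
    "ceac",
]


class ParameterPathError(KeyError):
    """A sensitivity-analysis parameter path does not resolve."""


class ThresholdError(ValueError):
    """No finite AI-cost threshold exists (no effectiveness gain)."""


# ---------------------------------------------------------------- paths

_PROB_LIKE = {
    "pretest_prob", "p_resect_early", "p_resect_delayed",
    "p_death_post_resection", "p_recurrence", "p_death_palliative",
    "p_death_fp_procedural", "p_verify_fp_as_no_bc",
    "utility_no_bc", "utility_fp", "utility_resection_year1",
    "utility_post_resection", "utility_undetected", "utility_palliative",
    "utility_dead", "sensitivity", "specificity",
}


def _strategy_map(strategies: Sequence[StrategyDefinition]) -> dict[str, StrategyDefinition]:
    return {s.name: s for s in strategies}


def valid_paths(params: ParameterSet, strategies: Sequence[StrategyDefinition]) -> list[str]:
    import dataclasses

    paths = [f.name for f in dataclasses.fields(ParameterSet) if f.name != "detection_schedule"]
    paths += [f"detection_schedule[{i}]" for i in range(len(params.detection_schedule))]
    for s in strategies:
        paths += [f"{s.name}.{f}" for f in ("sensitivity", "specificity", "screen_cost", "ai_cost")]
    return sorted(paths)


def resolve_parameter(
    path: str, params: ParameterSet, strategies: Sequence[StrategyDefinition]
) -> float:
    """Current value of a parameter path such as ``pretest_prob`` or ``ct.sensitivity``."""
    if "." in path:
        arm, _, fld = path.partition(".")
        smap = _strategy_map(strategies)
        if arm not in smap or not hasattr(smap[arm], fld):
            raise ParameterPathError(
                f"unknown path {path!r}; valid paths: {valid_paths(params, strategies)}"
            )
        return float(getattr(smap[arm], fld))
    if path.startswith("detection_schedule["):
        idx = int(path[len("detection_schedule["):-1])
        return params.detection_schedule[idx]
    if hasattr(params, path) and path != "detection_schedule":
        return float(getattr(params, path))
    raise ParameterPathError(
        f"unknown path {path!r}; valid paths: {valid_paths(params, strategies)}"
    )


def apply_parameter(
    path: str,
    value: float,
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
) -> tuple[ParameterSet, tuple[StrategyDefinition, ...]]:
    """Return copies of (params, strategies) with one path set to ``value``."""
    resolve_parameter(path, params, strategies)  # raises on unknown path
    if "." in path:
        arm, _, fld = path.partition(".")
        new = tuple(
            s.replace(**{fld: value}) if s.name == arm else s for s in strategies
        )
        return params, new
    if path.startswith("detection_schedule["):
        idx = int(path[len("detection_schedule["):-1])
        sched = list(params.detection_schedule)
        sched[idx] = value
        return params.replace(detection_schedule=tuple(sched)), tuple(strategies)
    return params.replace(**{path: value}), tuple(strategies)


def _bounds(path: str) -> tuple[float, float]:
    leaf = path.partition(".")[2] if "." in path else path
    if leaf.startswith("detection_schedule"):
        return 0.0, 1.0
    if leaf in _PROB_LIKE:
        return 0.0, 1.0
    return 0.0, math.inf


# ---------------------------------------------------------------- DSA

@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    low_value: float
    high_value: float
    result_at_low: ICERResult
    result_at_high: ICERResult
    icer_at_low: float    # signed ratio, for plotting/ranking only
    icer_at_high: float
    spread: float

    def __post_init__(self) -> None:
        if not self.low_value <= self.high_value:
            raise ValueError(
                f"{self.parameter}: low {self.low_value!r} > high {self.high_value!r}"
            )


def _compare(
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    lt: LifeTable,
    convention: AccrualConvention,
) -> ICERResult:
    smap = _strategy_map(strategies)
    mats = precompute_matrices(params, lt)
    res = {
        name: accrue(run_cohort(s, params, lt, convention, matrices=mats, provenance="dsa"))
        for name, s in smap.items()
    }
    return icer(res["ct_ai"], res["ct"], wtp=params.wtp)


def _signed_ratio(r: ICERResult) -> float:
    if r.icer is not None:
        return r.icer
    return math.copysign(math.inf, r.delta_cost) if r.delta_cost else 0.0


def one_way(
    parameter: str,
    low: float,
    high: float,
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    lt: LifeTable,
    convention: AccrualConvention = REFERENCE_CONVENTION,
) -> TornadoEntry:
    """Re-run both arms with ``parameter`` at its low and high setting."""
    results = []
    for v in (low, high):
        p2, s2 = apply_parameter(parameter, v, params, strategies)
        results.append(_compare(p2, s2, lt, convention))
    at_low, at_high = results
    rl, rh = _signed_ratio(at_low), _signed_ratio(at_high)
    spread = abs(rh - rl)
    return TornadoEntry(
        parameter=parameter,
        low_value=low,
        high_value=high,
        result_at_low=at_low,
        result_at_high=at_high,
        icer_at_low=rl,
        icer_at_high=rh,
        spread=spread,
    )


#: parameters varied by default in the tornado analysis
DEFAULT_DSA_PARAMETERS: tuple[str, ...] = (
    "pretest_prob",
    "ct.sensitivity",
    "ct.specificity",
    "ct_ai.sensitivity",
    "ct_ai.specificity",
    "p_resect_early",
    "p_resect_delayed",
    "p_death_post_resection",
    "p_recurrence",
    "p_death_palliative",
    "p_death_fp_procedural",
    "utility_fp",
    "utility_resection_year1",
    "utility_post_resection",
    "utility_palliative",
    "cost_fp_followup",
    "cost_resection",
    "cost_post_resection_annual",
    "cost_palliative_annual",
    "discount_rate",
)


def default_dsa_ranges(
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    relative_width: float = 0.20,
    parameters: Iterable[str] = DEFAULT_DSA_PARAMETERS,
) -> dict[str, tuple[float, float]]:
    """+/- ``relative_width`` around base values, clamped to validity ranges."""
    ranges = {}
    for path in parameters:
        base = resolve_parameter(path, params, strategies)
        lo_b, hi_b = _bounds(path)
        ranges[path] = (
            max(lo_b, base * (1.0 - relative_width)),
            min(hi_b, base * (1.0 + relative_width)),
        )
    return ranges


def tornado(
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    lt: LifeTable,
    ranges: dict[str, tuple[float, float]] | None = None,
    convention: AccrualConvention = REFERENCE_CONVENTION,
) -> list[TornadoEntry]:
    """One-way DSA over all parameters, sorted by spread (descending)."""
    if ranges is None:
        ranges = default_dsa_ranges(params, strategies)
    entries = [
        one_way(p, lo, hi, params, strategies, lt, convention)
        for p, (lo, hi) in ranges.items()
    ]
    entries.sort(key=lambda e: (math.isinf(e.spread), e.spread), reverse=True)
    return entries


# ---------------------------------------------------------------- threshold

def _base_increments(
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    lt: LifeTable,
    convention: AccrualConvention,
) -> tuple[float, float]:
    """(dC0, dE) of CT+AI over CT with the AI surcharge zeroed."""
    smap = _strategy_map(strategies)
    base = [smap["ct"], smap["ct_ai"].replace(ai_cost=0.0)]
    r = _compare(params, base, lt, convention)
    return r.delta_cost, r.delta_qaly


def threshold_ai_cost(
    target_icer: float,
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    lt: LifeTable,
    convention: AccrualConvention = REFERENCE_CONVENTION,
    cross_check: bool = True,
) -> float:
    """Per-screen AI surcharge at which the ICER equals ``target_icer``.

    The surcharge is an undiscounted cycle-0 cost of the AI arm only, so
    ICER(c) = (dC0 + c) / dE and ``c* = target_icer * dE - dC0``.  When
    ``cross_check`` is set, a bisection root-find on the full model must
    agree with the closed form to USD 0.01.
    """
    dc0, de = _base_increments(params, strategies, lt, convention)
    if de <= 0.0:
        raise ThresholdError(
            f"CT+AI gains no effectiveness over CT (dE = {de:.3g}); "
            "no finite AI-cost threshold exists"
        )
    c_star = target_icer * de - dc0
    if cross_check:
        smap = _strategy_map(strategies)

        def gap(c: float) -> float:
            s2 = [smap["ct"], smap["ct_ai"].replace(ai_cost=0.0, screen_cost=smap["ct_ai"].screen_cost + c)]
            r = _compare(params, s2, lt, convention)
            assert r.delta_qaly > 0
            return r.delta_cost - target_icer * r.delta_qaly

        lo, hi = c_star - max(1.0, abs(c_star)), c_star + max(1.0, abs(c_star))
        root = brentq(gap, lo, hi, xtol=1e-6)
        if abs(root - c_star) > 0.01:
            raise RuntimeError(
                f"threshold cross-check failed: closed form {c_star:.4f}, "
                f"bisection {root:.4f}"
            )
    return float(c_star)


def wtp_cost_table(
    wtp_values: Sequence[float],
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    lt: LifeTable,
    convention: AccrualConvention = REFERENCE_CONVENTION,
) -> pd.DataFrame:
    """Maximum cost-effective AI surcharge at each WTP threshold.

    The output is affine in WTP by construction (slope = base-case dE).
    """
    dc0, de = _base_increments(params, strategies, lt, convention)
    if de <= 0.0:
        raise ThresholdError(f"no effectiveness gain (dE = {de:.3g})")
    rows = [(w, w * de - dc0) for w in wtp_values]
    return pd.DataFrame(rows, columns=["wtp", "max_ai_cost"])


# ---------------------------------------------------------------- PSA

@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one parameter for the PSA.

    ``beta`` (probabilities/utilities) and ``gamma`` (costs) are
    moment-matched to ``mean`` with standard deviation
    ``rel_se * mean``; ``fixed`` pins the parameter at ``mean``.
    """

    parameter: str
    family: str
    mean: float
    rel_se: float = 0.10

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.family == "beta":
            if not 0.0 < self.mean < 1.0:
                raise ValidationError(
                    f"{self.parameter}: beta needs mean in (0, 1), got {self.mean!r}"
                )
            var = (self.rel_se * self.mean) ** 2
            if var >= self.mean * (1.0 - self.mean):
                raise ValidationError(
                    f"{self.parameter}: dispersion too large for a beta distribution"
                )
        if self.family == "gamma" and self.mean <= 0.0:
            raise ValidationError(f"{self.parameter}: gamma needs mean > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.mean
        if self.family == "beta":
            m, var = self.mean, (self.rel_se * self.mean) ** 2
            nu = m * (1.0 - m) / var - 1.0
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        shape = 1.0 / self.rel_se**2
        scale = self.mean * self.rel_se**2
        return float(rng.gamma(shape, scale))


_COST_PATHS = {
    "cost_fp_followup", "cost_resection", "cost_post_resection_annual",
    "cost_palliative_annual", "ct.screen_cost", "ct_ai.screen_cost",
}


def default_psa_specs(
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    rel_se: float = 0.10,
) -> list[DistributionSpec]:
    """Beta for probabilities/utilities, gamma for costs, boundary values fixed."""
    specs: list[DistributionSpec] = []
    prob_paths = [
        "pretest_prob", "ct.sensitivity", "ct.specificity",
        "ct_ai.sensitivity", "ct_ai.specificity",
        "p_resect_early", "p_resect_delayed", "p_death_post_resection",
        "p_recurrence", "p_death_palliative", "p_death_fp_procedural",
        "utility_fp", "utility_resection_year1", "utility_post_resection",
        "utility_palliative",
    ]
    for path in prob_paths:
        m = resolve_parameter(path, params, strategies)
        family = "beta" if 0.0 < m < 1.0 else "fixed"
        specs.append(DistributionSpec(path, family, m, rel_se))
    for path in sorted(_COST_PATHS - {"ct_ai.screen_cost"}):
        m = resolve_parameter(path, params, strategies)
        specs.append(DistributionSpec(path, "gamma" if m > 0 else "fixed", m, rel_se))
    return specs


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo samples of the increments of CT+AI over CT."""

    samples: pd.DataFrame   # columns: delta_cost, delta_qaly, cost_effective
    n_iterations: int
    seed: int
    frac_cost_effective: float
    n_truncated: int        # samples redrawn because they violated a range

    def __post_init__(self) -> None:
        if len(self.samples) != self.n_iterations:
            raise ValueError("sample count does not match n_iterations")
        if not 0.0 <= self.frac_cost_effective <= 1.0:
            raise ValueError("frac_cost_effective outside [0, 1]")


_MAX_REDRAWS = 100


def psa(
    dist_specs: Sequence[DistributionSpec],
    n_iterations: int,
    seed: int,
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    lt: LifeTable,
    convention: AccrualConvention = REFERENCE_CONVENTION,
) -> PSAResult:
    """Probabilistic sensitivity analysis of CT+AI vs CT.

    Each iteration draws one value per spec (redrawing, with a counter,
    any draw that violates the target parameter's validity range),
    rebuilds the model, and records the incremental cost and
    effectiveness.  ``frac_cost_effective`` is the fraction of iterations
    in which CT+AI is cost-effective at ``params.wtp`` (dominant, or a
    tradeoff at or below the WTP).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    smap = _strategy_map(strategies)
    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    dc = np.empty(n_iterations)
    dq = np.empty(n_iterations)
    ce = np.empty(n_iterations, dtype=bool)
    n_trunc = 0
    # validate every path once up front
    for spec in dist_specs:
        resolve_parameter(spec.parameter, params, strategies)
    for i in range(n_iterations):
        rng = np.random.default_rng(streams[i])
        param_changes: dict[str, float] = {}
        strat_changes: dict[str, dict[str, float]] = {"ct": {}, "ct_ai": {}}
        sched = list(params.detection_schedule)
        sched_touched = False
        for spec in dist_specs:
            lo, hi = _bounds(spec.parameter)
            for _ in range(_MAX_REDRAWS):
                v = spec.sample(rng)
                if lo <= v <= hi:
                    break
                n_trunc += 1
            else:  # pragma: no cover - needs a pathological spec
                raise ValidationError(
                    f"{spec.parameter}: could not draw an in-range value"
                )
            path = spec.parameter
            if "." in path:
                arm, _, fld = path.partition(".")
                strat_changes[arm][fld] = v
            elif path.startswith("detection_schedule["):
                sched[int(path[len("detection_schedule["):-1])] = v
                sched_touched = True
            else:
                param_changes[path] = v
        if sched_touched:
            param_changes["detection_schedule"] = tuple(sched)
        p_i = params.replace(**param_changes) if param_changes else params
        s_i = tuple(
            smap[name].replace(**chg) if chg else smap[name]
            for name, chg in strat_changes.items()
        )
        r = _compare(p_i, s_i, lt, convention)
        dc[i], dq[i] = r.delta_cost, r.delta_qaly
        ce[i] = r.cost_effective_at_wtp
    samples = pd.DataFrame(
        {"delta_cost": dc, "delta_qaly": dq, "cost_effective": ce}
    )
    return PSAResult(
        samples=samples,
        n_iterations=n_iterations,
        seed=seed,
        frac_cost_effective=float(ce.mean()),
        n_truncated=n_trunc,
    )


def ceac(result: PSAResult, wtp_values: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA samples.

    Uses the same acceptance rule as :func:`lungscreen_cea.cea.icer`
    (dominant, or QALY-gaining with ICER at or below the WTP), which is
    monotone in WTP for every sample, so the curve is non-decreasing.
    """
    dc = result.samples["delta_cost"].to_numpy()
    dq = result.samples["delta_qaly"].to_numpy()
    dominant = (dc <= 0) & (dq >= 0) & ((dc < 0) | (dq > 0))
    rows = [
        (w, float((dominant | ((dq > 0) & (dc <= w * dq))).mean()))
        for w in wtp_values
    ]
    return pd.DataFrame(rows, columns=["wtp", "prob_cost_effective"])
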