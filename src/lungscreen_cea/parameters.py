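"""Model parameters for the screening cost-effectiveness analysis.

The analysis compares two arms of a one-off (baseline) low-dose-CT lung
cancer screen in a 60-year-old smoking cohort: reading by a radiologist
alone (``ct``) versus reading supported by a deep-learning nodule
detection system (``ct_ai``).  A :class:`ParameterSet` carries every
model input — pre-test probability, costs, utilities and transition
probabilities — and a :class:`StrategyDefinition` carries the diagnostic
performance and per-screen cost of one arm.

Probabilities and utilities are stored as fractions in [0, 1].  Config
files may give any probability-like value either as a plain fraction or
as an explicit-unit mapping ``{percent: 2.635}`` to rule out the classic
100x error.
"""

from __future__ import annotations

import dataclasses
import io
import math
import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml

__all__ = [
    "ConfigError",
    "ValidationError",
    "StrategyDefinition",
    "ParameterSet",
    "load_parameters",
    "loads_parameters",
    "serialize_parameters",
    "default_parameters",
    "default_strategies",
    "TABLE_FIELD_MAP",
]


class ConfigError(ValueError):
    """A configuration document could not be parsed or has unknown keys."""


class ValidationError(ValueError):
    """A parameter value violates its validity range."""


# fields interpreted as probabilities / utilities (unit-aware, range [0, 1])
_FRACTION_FIELDS = {
    "pretest_prob",
    "discount_rate",  # not a probability, but percent-or-fraction applies
    "utility_no_bc",
    "utility_fp",
    "utility_resection_year1",
    "utility_post_resection",
    "utility_undetected",
    "utility_palliative",
    "utility_dead",
    "p_resect_early",
    "p_resect_delayed",
    "p_death_post_resection",
    "p_recurrence",
    "p_death_palliative",
    "p_death_fp_procedural",
    "p_verify_fp_as_no_bc",
    "sensitivity",
    "specificity",
}

_PROB_BOUND_EXEMPT = {"discount_rate"}  # >= 0 but may exceed 1 in principle


def _coerce_fraction(name: str, value: Any) -> float:
    """Accept ``0.026``, ``{"fraction": 0.026}`` or ``{"percent": 2.6}``."""
    if isinstance(value, Mapping):
        keys = set(value)
        if keys == {"percent"}:
            return float(value["percent"]) / 100.0
        if keys == {"fraction"}:
            return float(value["fraction"])
        raise ConfigError(
            f"{name}: unit mapping must have exactly one key 'percent' or "
            f"'fraction', got {sorted(keys)}"
        )
    return float(value)


@dataclass(frozen=True)
class StrategyDefinition:
    """One screening arm: diagnostic performance and per-screen costs.

    ``ai_cost`` is the additional per-screen cost of the AI system; it is
    0 in the base case and is the variable of the threshold analysis.
    """

    name: str
    sensitivity: float
    specificity: float
    screen_cost: float
    ai_cost: float = 0.0

    def __post_init__(self) -> None:
        for f in ("sensitivity", "specificity"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.name}.{f} = {v!r} outside [0, 1]")
        for f in ("screen_cost", "ai_cost"):
            v = getattr(self, f)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValidationError(f"{self.name}.{f} = {v!r} must be >= 0")

    @property
    def acute_cost(self) -> float:
        """Total per-screen acute cost (screen plus AI surcharge)."""
        return self.screen_cost + self.ai_cost

    def replace(self, **changes: Any) -> "StrategyDefinition":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ParameterSet:
    """Every model input except the life table and the two strategies.

    Costs are USD; utilities are QALY weights; annual probabilities are
    fractions.  ``detection_schedule`` gives the per-year probability that
    an initially missed cancer becomes clinically apparent in its 1st,
    2nd and 3rd year undetected; the final entry must be 1 so the state
    drains.
    """

    pretest_prob: float = 0.02635
    start_age: int = 60
    horizon_cycles: int = 20
    discount_rate: float = 0.03
    wtp: float = 100_000.0

    cost_fp_followup: float = 2256.0
    cost_resection: float = 36_305.0
    cost_post_resection_annual: float = 4283.0
    cost_palliative_annual: float = 60_000.0
    cost_undetected: float = 0.0

    utility_no_bc: float = 1.0
    utility_fp: float = 0.98
    utility_resection_year1: float = 0.79
    utility_post_resection: float = 0.933
    utility_undetected: float = 1.0
    utility_palliative: float = 0.63
    utility_dead: float = 0.0

    p_resect_early: float = 0.75
    p_resect_delayed: float = 0.26
    p_death_post_resection: float = 0.047
    p_recurrence: float = 0.098
    p_death_palliative: float = 0.36
    p_death_fp_procedural: float = 0.001
    p_verify_fp_as_no_bc: float = 1.0
    detection_schedule: tuple[float, ...] = (0.15, 0.40, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "detection_schedule", tuple(float(x) for x in self.detection_schedule)
        )
        probs = [
            "pretest_prob",
            "utility_no_bc",
            "utility_fp",
            "utility_resection_year1",
            "utility_post_resection",
            "utility_undetected",
            "utility_palliative",
            "utility_dead",
            "p_resect_early",
            "p_resect_delayed",
            "p_death_post_resection",
            "p_recurrence",
            "p_death_palliative",
            "p_death_fp_procedural",
            "p_verify_fp_as_no_bc",
        ]
        for f in probs:
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{f} = {v!r} outside [0, 1]")
        for f in (
            "cost_fp_followup",
            "cost_resection",
            "cost_post_resection_annual",
            "cost_palliative_annual",
            "cost_undetected",
            "wtp",
        ):
            v = getattr(self, f)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValidationError(f"{f} = {v!r} must be >= 0")
        if self.discount_rate < 0.0:
            raise ValidationError(f"discount_rate = {self.discount_rate!r} must be >= 0")
        if self.horizon_cycles < 1:
            raise ValidationError(f"horizon_cycles = {self.horizon_cycles!r} must be >= 1")
        if not 1 <= len(self.detection_schedule) <= 3:
            raise ValidationError(
                "detection_schedule must have 1-3 entries (one per undetected "
                f"tunnel year), got {len(self.detection_schedule)}"
            )
        for i, d in enumerate(self.detection_schedule):
            if not 0.0 <= d <= 1.0:
                raise ValidationError(f"detection_schedule[{i}] = {d!r} outside [0, 1]")
        if self.detection_schedule[-1] != 1.0:
            raise ValidationError(
                "detection_schedule last entry must be 1.0 so the undetected "
                f"state drains, got {self.detection_schedule[-1]!r}"
            )

    def replace(self, **changes: Any) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def fingerprint(self) -> str:
        """Canonical digest used to check provenance of derived results."""
        import hashlib
        import json

        blob = json.dumps(serialize_parameters(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# One entry per row of the published input table, mapping the quantity to
# the field that carries it.  The completeness test enumerates this.
TABLE_FIELD_MAP: dict[str, str] = {
    "Pre-test probability of BC": "pretest_prob",
    "Age at diagnostic procedure": "start_age",
    "Assumed WTP": "wtp",
    "Discount rate": "discount_rate",
    "Markov model time": "horizon_cycles",
    "Sensitivity for BC CT": "ct.sensitivity",
    "Specificity for BC CT": "ct.specificity",
    "Sensitivity for BC CT + AI": "ct_ai.sensitivity",
    "Specificity for BC CT + AI": "ct_ai.specificity",
    "CT (acute cost)": "ct.screen_cost",
    "Follow up if false positive (cost)": "cost_fp_followup",
    "Curative therapy BC/resection cost": "cost_resection",
    "BC undetected (cost)": "cost_undetected",
    "BC after resection (annual cost)": "cost_post_resection_annual",
    "Therapy BC, palliative (annual cost)": "cost_palliative_annual",
    "No BC (utility)": "utility_no_bc",
    "Follow up if false positive (utility)": "utility_fp",
    "Curative therapy BC/resection (utility)": "utility_resection_year1",
    "BC undetected (utility)": "utility_undetected",
    "BC after resection (utility)": "utility_post_resection",
    "BC palliative (utility)": "utility_palliative",
    "Dead (utility)": "utility_dead",
    "Verification of suspicious nodule as no BC": "p_verify_fp_as_no_bc",
    "Death if no BC but suspicious nodule (excess)": "p_death_fp_procedural",
    "Resection rate of BC after early detection": "p_resect_early",
    "Death after curative resection": "p_death_post_resection",
    "Recurrence after resection": "p_recurrence",
    "Detection of initially undetected BC": "detection_schedule",
    "Resection rate of BC after delayed detection": "p_resect_delayed",
    "Death with palliative care": "p_death_palliative",
}

_DEFAULT_STRATEGIES = {
    "ct": dict(sensitivity=0.779, specificity=0.877, screen_cost=161.0, ai_cost=0.0),
    "ct_ai": dict(sensitivity=0.977, specificity=0.984, screen_cost=161.0, ai_cost=0.0),
}


def default_parameters() -> ParameterSet:
    """The base-case parameter set."""
    return ParameterSet()


def default_strategies(
    params: ParameterSet | None = None,
    ai_cost: float = 0.0,
) -> tuple[StrategyDefinition, StrategyDefinition]:
    """Return the two arms ``(ct, ct_ai)`` at their base-case values.

    ``ai_cost`` overrides the additional per-screen AI cost of the
    ``ct_ai`` arm (USD 0 in the base case).
    """
    ct = StrategyDefinition(name="ct", **_DEFAULT_STRATEGIES["ct"])
    spec = dict(_DEFAULT_STRATEGIES["ct_ai"], ai_cost=float(ai_cost))
    ct_ai = StrategyDefinition(name="ct_ai", **spec)
    return ct, ct_ai


def _build_strategy(name: str, raw: Mapping[str, Any]) -> StrategyDefinition:
    known = {"sensitivity", "specificity", "screen_cost", "ai_cost", "name"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"strategy {name!r}: unknown keys {sorted(unknown)}")
    merged = dict(_DEFAULT_STRATEGIES.get(name, _DEFAULT_STRATEGIES["ct"]))
    for k, v in raw.items():
        if k == "name":
            continue
        merged[k] = _coerce_fraction(f"{name}.{k}", v) if k in _FRACTION_FIELDS else float(v)
    return StrategyDefinition(name=name, **merged)


def loads_parameters(
    text: str,
) -> tuple[ParameterSet, tuple[StrategyDefinition, StrategyDefinition]]:
    """Parse a YAML or JSON config document (JSON is a YAML subset)."""
    try:
        raw = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:  # includes line/column in its message
        raise ConfigError(f"config does not parse: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    raw = dict(raw)
    strategies_raw = raw.pop("strategies", {})
    if not isinstance(strategies_raw, Mapping):
        raise ConfigError("'strategies' must be a mapping of arm name -> settings")

    param_fields = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(raw) - param_fields
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key == "detection_schedule":
            if not isinstance(value, Sequence) or isinstance(value, str):
                raise ConfigError("detection_schedule must be a list of probabilities")
            kwargs[key] = tuple(
                _coerce_fraction(f"detection_schedule[{i}]", v) for i, v in enumerate(value)
            )
        elif key in _FRACTION_FIELDS:
            kwargs[key] = _coerce_fraction(key, value)
        elif key in ("start_age", "horizon_cycles"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    params = ParameterSet(**kwargs)

    ct, ct_ai = default_strategies(params)
    if "ct" in strategies_raw:
        ct = _build_strategy("ct", strategies_raw["ct"])
    if "ct_ai" in strategies_raw:
        ct_ai = _build_strategy("ct_ai", strategies_raw["ct_ai"])
    extra = set(strategies_raw) - {"ct", "ct_ai"}
    if extra:
        raise ConfigError(f"unknown strategies {sorted(extra)}; expected 'ct', 'ct_ai'")
    return params, (ct, ct_ai)


def load_parameters(
    source: str | os.PathLike,
) -> tuple[ParameterSet, tuple[StrategyDefinition, StrategyDefinition]]:
    """Load and validate a parameter config from a YAML/JSON file."""
    with open(source, "r", encoding="utf-8") as fh:
        return loads_parameters(fh.read())


def serialize_parameters(
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition] | None = None,
) -> dict[str, Any]:
    """Dump to a plain dict that :func:`loads_parameters` round-trips."""
    out: dict[str, Any] = dataclasses.asdict(params)
    out["detection_schedule"] = list(params.detection_schedule)
    if strategies is not None:
        out["strategies"] = {
            s.name: {
                "sensitivity": s.sensitivity,
                "specificity": s.specificity,
                "screen_cost": s.screen_cost,
                "ai_cost": s.ai_cost,
            }
            for s in strategies
        }
    return out
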