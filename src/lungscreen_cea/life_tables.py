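"""Age-specific background mortality.

The Markov model needs one annual probability of death ``q(age)`` for
every cycle; it is taken from a period life table by integer-age lookup
(cycles are annual, so no interpolation or smoothing is applied and a
single unisex column is used).

The bundled table ``data/life_table_us_synthetic.csv`` is a synthetic
approximation of a recent US total-population period life table for ages
55-85; it stands in for a published national life table and is clearly
labelled as synthetic.  Any CSV with columns ``age,qx`` can be supplied
instead.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["LifeTableError", "LifeTable", "load_life_table", "bundled_life_table"]

BUNDLED_LIFE_TABLE = "life_table_us_synthetic.csv"


class LifeTableError(ValueError):
    """A life table is malformed or does not cover a required age."""


@dataclass(frozen=True)
class LifeTable:
    """Ordered (age, annual death probability) pairs.

    ``ages`` must be strictly increasing integers and every ``q`` must lie
    in [0, 1].
    """

    ages: np.ndarray
    qx: np.ndarray
    source_label: str = "unlabelled"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or qx.shape != ages.shape or ages.size == 0:
            raise LifeTableError("life table needs matching 1-D age and qx columns")
        if np.any(np.diff(ages) <= 0):
            raise LifeTableError("ages must be strictly increasing")
        bad = (qx < 0.0) | (qx > 1.0) | ~np.isfinite(qx)
        if np.any(bad):
            ages_bad = ages[bad].tolist()
            raise LifeTableError(f"q outside [0, 1] at age(s) {ages_bad}")

    def annual_death_prob(self, age: int) -> float:
        """Background probability of dying within the year at integer ``age``."""
        age = int(age)
        idx = np.searchsorted(self.ages, age)
        if idx >= self.ages.size or self.ages[idx] != age:
            raise LifeTableError(
                f"age {age} not covered by life table "
                f"[{self.ages[0]}, {self.ages[-1]}] ({self.source_label})"
            )
        return float(self.qx[idx])

    def require_coverage(self, start_age: int, horizon_cycles: int) -> None:
        """Raise unless every age in [start_age, start_age + horizon] is present."""
        needed = np.arange(start_age, start_age + horizon_cycles + 1)
        missing = sorted(set(needed.tolist()) - set(self.ages.tolist()))
        if missing:
            raise LifeTableError(
                f"life table ({self.source_label}) is missing required age(s) {missing}"
            )


def load_life_table(source: str | os.PathLike, source_label: str | None = None) -> LifeTable:
    """Read a two-column ``age,qx`` CSV (header optional, ``#`` comments allowed)."""
    df = pd.read_csv(source, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    if "age" in cols and ("qx" in cols or "q" in cols):
        df.columns = cols
        qcol = "qx" if "qx" in cols else "q"
        ages, qx = df["age"].to_numpy(), df[qcol].to_numpy()
    elif df.shape[1] == 2:
        # headerless file: first row was promoted to header, recover it
        df = pd.read_csv(source, comment="#", header=None)
        ages, qx = df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
    else:
        raise LifeTableError(
            f"expected columns 'age' and 'qx', got {list(df.columns)!r}"
        )
    label = source_label or str(source)
    return LifeTable(ages=ages, qx=qx, source_label=label)


def bundled_life_table() -> LifeTable:
    """The synthetic US-style life table shipped with the package."""
    ref = resources.files("lungscreen_cea").joinpath("data", BUNDLED_LIFE_TABLE)
    with resources.as_file(ref) as path:
        return load_life_table(path, source_label=BUNDLED_LIFE_TABLE)
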