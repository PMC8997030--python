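"""Report writers and the run manifest.

Numeric report fields are written at full precision (plus a 2-dp display
column for currency) so that values round-trip through the CSV/JSON
writers; every output file is referenced by exactly one manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import __version__
from .cea import ICERResult
from .markov import CEResult, CohortTrace
from .states import State

__all__ = ["RunManifest", "write_json", "trace_frame", "icer_report", "config_digest"]


def config_digest(payload: Any) -> str:
    """sha256 digest of a canonical JSON rendering of the inputs."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_json(path: str | os.PathLike, payload: Any) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def trace_frame(trace: CohortTrace) -> pd.DataFrame:
    """Long-format (cycle, state, occupancy) table plus per-cycle accruals."""
    H = trace.occupancy.shape[0]
    rows = [
        {
            "cycle": t,
            "age": int(trace.age_per_cycle[t]),
            "state": State(s).name.lower(),
            "occupancy": trace.occupancy[t, s],
        }
        for t in range(H)
        for s in range(trace.occupancy.shape[1])
    ]
    return pd.DataFrame(rows)


def icer_report(
    results: dict[str, CEResult], comparison: ICERResult, wtp: float
) -> dict[str, Any]:
    """JSON-ready comparison report with full-precision and display columns."""
    def _money(x: float) -> dict[str, Any]:
        return {"usd": x, "usd_display": round(x, 2)}

    out: dict[str, Any] = {"wtp_per_qaly": wtp, "arms": {}}
    for name, r in results.items():
        out["arms"][name] = {
            "total_cost": _money(r.total_cost),
            "total_qaly": r.total_qaly,
        }
    out["incremental"] = {
        "intervention": comparison.intervention,
        "comparator": comparison.comparator,
        "delta_cost": _money(comparison.delta_cost),
        "delta_qaly": comparison.delta_qaly,
        "icer": comparison.icer,
        "classification": comparison.classification,
        "cost_effective_at_wtp": comparison.cost_effective_at_wtp,
    }
    return out


@dataclass
class RunManifest:
    """Provenance record for one CLI invocation."""

    subcommand: str
    config_digest: str
    life_table_source: str
    seed: int | None
    outputs: list[str] = field(default_factory=list)
    software_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def register(self, path: str | os.PathLike) -> str:
        p = str(path)
        self.outputs.append(p)
        return p

    def write(self, path: str | os.PathLike) -> None:
        write_json(path, dataclasses.asdict(self))
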