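#!/usr/bin/env python
"""One-way deterministic sensitivity analysis (tornado table).

Varies each model input +/-20% (clamped to its validity range), re-runs
the comparison at both ends, and ranks parameters by the spread of the
signed ICER.  Dominance is mapped to the signed ratio for ranking and
plotting only; the classification column carries the interpretation.
Writes results/tornado.csv.
"""

from pathlib import Path

import pandas as pd

from lungscreen_cea import bundled_life_table, default_parameters, default_strategies
from lungscreen_cea.sensitivity import default_dsa_ranges, tornado

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    params = default_parameters()
    strategies = default_strategies(params)
    lt = bundled_life_table()
    OUT.mkdir(exist_ok=True)

    ranges = default_dsa_ranges(params, strategies, relative_width=0.20)
    entries = tornado(params, strategies, lt, ranges)
    frame = pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "class_at_low": [e.result_at_low.classification for e in entries],
            "class_at_high": [e.result_at_high.classification for e in entries],
            "spread": [e.spread for e in entries],
        }
    )
    frame.to_csv(OUT / "tornado.csv", index=False)
    print(frame.round(4).to_string(index=False))

    flips = frame[(frame.class_at_low != "dominant") | (frame.class_at_high != "dominant")]
    print(
        f"\n{len(frame)} parameters varied; CT+AI stays dominant at both ends for "
        f"{len(frame) - len(flips)} of them."
    )
    print(
        "The specificities are the influential inputs: in a low-prevalence "
        "screening cohort almost all positives are false positives, so the "
        "work-up cost differential dwarfs every other lever."
    )


if __name__ == "__main__":
    main()
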