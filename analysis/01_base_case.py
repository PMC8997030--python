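#!/usr/bin/env python
"""Base case: one screened cohort per arm, discounted totals and ICER.

Runs the Markov cohort for CT-only and CT+AI reading of a single baseline
low-dose-CT screen (AI surcharge USD 0), exports the per-cycle traces and
the incremental comparison under results/.
"""

from pathlib import Path

from lungscreen_cea import (
    accrue,
    bundled_life_table,
    default_parameters,
    default_strategies,
    icer,
    run_cohort,
)
from lungscreen_cea.reports import icer_report, trace_frame, write_json

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    params = default_parameters()
    strategies = default_strategies(params)
    lt = bundled_life_table()
    OUT.mkdir(exist_ok=True)

    results = {}
    for s in strategies:
        trace = run_cohort(s, params, lt)
        trace_frame(trace).to_csv(OUT / f"trace_{s.name}.csv", index=False)
        results[s.name] = accrue(trace)
        r = results[s.name]
        print(f"{s.name:6s}: {r.total_cost:8.2f} USD  {r.total_qaly:.4f} QALYs")

    comparison = icer(results["ct_ai"], results["ct"], wtp=params.wtp)
    write_json(OUT / "base_case.json", icer_report(results, comparison, params.wtp))
    print(
        f"\nCT+AI vs CT: dCost {comparison.delta_cost:+.2f} USD, "
        f"dQALY {comparison.delta_qaly:+.5f} -> {comparison.classification}"
    )
    print(
        "AI support with no surcharge costs less and is more effective than "
        "unassisted reading: the extra true positives are treated curatively "
        "and the avoided false positives save work-up costs."
    )


if __name__ == "__main__":
    main()
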