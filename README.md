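# lungscreen-cea

Cost-effectiveness analysis of AI-assisted **baseline low-dose-CT lung
cancer screening**, implemented as a tested Python pipeline: a screening
decision tree feeding an annual-cycle Markov cohort model, incremental
cost-effectiveness (ICER/dominance), deterministic and probabilistic
sensitivity analysis, and a threshold analysis on the per-screen price
of the AI system.

## The question

Deep-learning nodule detectors read a first screening CT with higher
sensitivity (97.7% vs 77.9%) and specificity (98.4% vs 87.7%) than a
radiologist without prior imaging.  Is adding such a system to the
baseline screen worth paying for — and up to what per-screen price?

The model follows a cohort of 60-year-old high-risk smokers
(pre-test probability of bronchial cancer 2.635%) for 20 annual cycles
after a single screen.  Detected cancers are resected when possible
(75% early, 26% after delayed detection; resection USD 36,305); missed
cancers surface clinically within three years (15%/40%/100%);
unresectable disease is palliative (USD 60,000/yr, utility 0.63, annual
mortality 36%); false positives spend a work-up year (USD 2256, utility
0.98, +0.001 procedural mortality).  Costs and QALYs are discounted at
3%/yr.  Strategy arms differ only in sensitivity/specificity and the AI
surcharge; comparison is by incremental cost-effectiveness ratio

```
ICER = (C_ai − C_ct) / (E_ai − E_ct)   [USD per QALY]
```

with a negative ICER interpreted via dominance (lower cost *and* higher
effectiveness), never as a bare ratio, and a willingness-to-pay (WTP) of
USD 100,000/QALY.

## Worked example

```python
from lungscreen_cea import (bundled_life_table, default_parameters,
                            default_strategies, icer, run_strategy)

params = default_parameters()          # the published base-case inputs
ct, ct_ai = default_strategies(params)
lt = bundled_life_table()              # synthetic US-style life table

r_ai, r_ct = run_strategy(ct_ai, params, lt), run_strategy(ct, params, lt)
print(r_ai.total_cost, r_ai.total_qaly)   # 4298.32  13.7585
print(r_ct.total_cost, r_ct.total_qaly)   # 4558.85  13.7535
print(icer(r_ai, r_ct, wtp=params.wtp).classification)  # 'dominant'
```

At zero surcharge, AI-assisted reading **dominates**: it saves USD
260.53 and gains 0.00493 QALYs per person screened.  The saving comes
from ~0.104 fewer false-positive work-ups per screen; the QALY gain from
curative instead of delayed treatment of the extra true positives and
from avoided work-up disutility/mortality.  Because the surcharge is a
one-time cycle-0 cost, the ICER is affine in it: CT+AI stays outright
cost-saving up to **USD 260.53** per screen and cost-effective at the
WTP up to **USD 753.97**:

```bash
$ lungscreen-cea threshold --target-icer 0
AI cost at ICER 0 USD/QALY: 260.53 USD
$ lungscreen-cea threshold --target-icer 100000
AI cost at ICER 100000 USD/QALY: 753.97 USD
```

The numbered drivers under `analysis/` run the full study and write
tables to `results/`:

```bash
python analysis/01_base_case.py           # per-arm totals, ICER, traces
python analysis/02_threshold_analysis.py  # AI price limits per WTP
python analysis/03_tornado.py             # one-way DSA, ranked spreads
python analysis/04_psa.py --seed 0        # 30,000-iteration PSA + CEAC
```

The tornado analysis shows the result is insensitive to everything
except the two specificities (in a 2.6%-prevalence cohort nearly all
positives are false, so work-up costs dominate); the PSA finds ~77% of
iterations cost-effective at the WTP with 10% relative-SE uncertainty on
all inputs.

Equivalent CLI subcommands: `run`, `compare`, `tornado`, `threshold`,
`wtp-table`, `psa`, `make-fixtures` (see `--help`; `--config` accepts a
YAML/JSON parameter file, `--life-table` any `age,qx` CSV).

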