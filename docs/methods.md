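# Methods

This package re-implements, as tested and reusable code, a published
decision-analytic evaluation of AI support for the *baseline* (first)
low-dose-CT lung cancer screening scan.  The original analysis was built
in a commercial decision-tree/Markov package; this document records the
model as implemented here, every convention the original did not pin
down, and what the reproduction does and does not achieve.

## Decision problem

A cohort of 60-year-old high-risk smokers receives one screening CT.
Two reading strategies are compared:

* **ct** — radiologist reading: sensitivity 77.9%, specificity 87.7%;
* **ct_ai** — reading supported by a deep-learning nodule detection
  system: sensitivity 97.7%, specificity 98.4%.

Both cost USD 161 per screen; the AI surcharge is USD 0 in the base case
and is the subject of the threshold analysis.  Pre-test probability of
bronchial cancer (BC) is 2.635%.  Effectiveness is measured in QALYs,
costs in USD from a US healthcare perspective, both discounted at 3%/yr
over a 20-year horizon, with a willingness-to-pay (WTP) of USD
100,000/QALY.

## Model structure

**Decision tree (cycle 0).**  The screen splits the cohort into
TP/FN/TN/FP by pre-test probability × sensitivity/specificity.  TP mass
resolves through a transient "early detection" node *within* cycle 0:
75% is resected (one-time cost USD 36,305) and enters the first
post-resection year; 25% is unresectable and enters palliative care.
FN mass enters the first undetected year, TN enters "no BC", FP enters
the "suspicious nodule" work-up state.  Transient nodes never occupy a
cycle.

**Markov states.**  The six clinical states are expanded to nine
memoryless states: `no_bc`, `no_bc_suspicious`, `undetected_y1..y3`
(tunnel), `after_resection_y1` (tunnel), `after_resection_later`,
`palliative`, `dead`.  The tunnels carry duration-dependent values: a
missed cancer surfaces clinically with probability 15%/40%/100% in its
1st/2nd/3rd undetected year (the final 100% drains the tunnel — a
validated invariant), and the first post-resection year has utility 0.79
vs 0.933 afterwards.  Re-entry into resection via delayed detection
restarts the tunnel, charges the one-time resection cost again, and uses
the delayed resectability of 26%.

**Transitions (annual, age-dependent).**  Death is resolved first within
a cycle; detection, recurrence and verification apply to survivors.
Background mortality q(age) comes from a life table by integer-age
lookup (no interpolation — cycles are annual; no smoker-specific uplift;
unisex q).  State-specific mortality:

| state              | annual death probability                  |
|--------------------|-------------------------------------------|
| no BC, undetected  | q(age) (life table, as published)         |
| suspicious nodule  | min(1, q(age) + 0.001) — invasive work-up excess, the only additive excess |
| after resection    | 0.047 **total** (not added to life table)  |
| palliative         | 0.36 **total**                             |

The post-resection 4.7% and palliative 36% are the states' *total*
annual death probabilities because the source describes them as the
annual mortality rates of those patients.  Survivors of the resection
states recur with probability 9.8%/yr; recurrence transitions to
palliative care (the state set offers no other recurrence-bearing
state).  Suspicious nodules are verified benign within one year
(verification probability a parameter, default 1.0) and return to
`no_bc`.

**Values.**  Annual state costs: work-up USD 2256 (accrued for the
single year spent in the suspicious state), post-resection USD 4283/yr
(both tunnel years; year 1 additionally carries the one-time USD 36,305
entry cost), palliative USD 60,000/yr, undetected USD 0 and utility 1 —
taken literally from the published input table even though clinically
counterintuitive.  Utilities: healthy 1, work-up year 0.98, resection
year 1 0.79, later 0.933, palliative 0.63, dead 0.

## Accrual conventions and calibration

The original publication does not state its accrual convention.  The
engine therefore makes it explicit (`AccrualConvention`): accrual basis
(start- vs end-of-cycle membership), half-cycle averaging, and whether
the entry year (cycle 0) accrues its states' annual values
undiscounted.  Cycle-t accruals are discounted by (1+r)^-t; one-time
cycle-0 costs (screen, AI surcharge, entry resections) are undiscounted;
a delayed resection during cycle t is charged at (1+r)^-t.

All closed-form oracles in the test suite use the **plain convention**
(end-of-cycle membership, no half-cycle, no entry-year accrual), under
which, e.g., an immortal utility-1 undiscounted cohort accrues exactly
`horizon` QALYs and an all-palliative cohort accrues
Σ_{t=1..20} 0.63·0.64^t.

For reproducing the reference results the convention grid was evaluated
once against the four published base-case totals.  The error-minimizing
member — **half-cycle averaging with entry-year accrual** — is the
package default (`REFERENCE_CONVENTION`).  With the bundled life table
it gives:

| quantity        | this package | reference | deviation |
|-----------------|--------------|-----------|-----------|
| CT+AI cost (USD)| 4298.32      | 4310.82   | −0.3%     |
| CT cost (USD)   | 4558.85      | 4378.44   | +4.1%     |
| CT+AI QALYs     | 13.7585      | 13.76     | −0.01%    |
| CT QALYs        | 13.7535      | 13.75     | +0.03%    |

Under this convention a cohort accrues values at 21 time points over 20
cycles, so the QALY ceiling is `horizon + 1` (the entry year counts).

## Known irreproducibility of the increments

The reference analysis reports the *increments* ΔC ≈ −67.6 USD and —
implied jointly by its threshold table, which is affine in WTP with
slope ΔE — ΔE ≈ 0.0117 QALY, hence AI-cost thresholds of USD 68 (ICER 0)
and USD 1240 (WTP).  These could not be reproduced from the published
inputs under *any* accrual convention in the grid: the inputs as printed
yield ΔE in 0.0039–0.0052 and ΔC in −54 to −327 (convention-dependent),
i.e. this model is **more** favourable to AI on cost (threshold USD
260.53 at ICER 0, USD 753.97 at the WTP) and less favourable on
effectiveness.  The reference ΔE would require a ≈2.0-QALY gap between
the early-detected and missed-cancer pathways, whereas the published
inputs (undetected utility 1, undetected mortality from the life table,
delayed resectability 26%) produce ≈0.49.  Deliberate deviations from
the printed inputs (undetected utility 0.63, undetected mortality 36%,
zero delayed resectability) were explored and cannot satisfy the totals
and the increments simultaneously either; the original model evidently
used wiring or inputs beyond its printed input table.  The two
acceptance tests asserting the reference increments and thresholds are
therefore expected to fail and are kept failing rather than loosened;
the structural claims (dominance of CT+AI, affinity of the WTP table,
sign behaviour of the DSA) all reproduce.

## Life table

No edition of the national life table is bundled, because the exact
source edition is unspecified and this package ships no third-party
data.  `data/life_table_us_synthetic.csv` is a clearly-labelled
*synthetic* approximation of a recent US total-population period table
(q rising from ≈0.010 at 60 to ≈0.048 at 80, ages 55–85).  Any official
`age,qx` CSV can be swapped in (`--life-table`); the increments are
insensitive to plausible life-table perturbations, so the
irreproducibility above is not a life-table artifact.

## Sensitivity analyses

**One-way DSA (tornado).**  Default ranges are ±20% around base values,
clamped to validity ranges — an explicit, configurable stand-in for the
unquantified "wide ranges" of the original.  Both arms are re-run at
each end; entries are ranked by the spread of the signed ICER ratio,
with dominance mapped to the signed ratio *for ranking and plotting
only* (the classification is carried alongside).  Within these ranges
CT+AI stays dominant when varying sensitivities and resectabilities;
varying specificities flips the ICER positive.  Near the point where the
AI arm's sampled specificity falls to the comparator's, the QALY
increment crosses zero and the ICER necessarily diverges through +∞ —
so "the WTP is never crossed" cannot hold over ranges that include that
crossing; the acceptance test asserting it is expectedly red (the
original's plotted ranges, which are not printed, evidently excluded
the crossing).

**Threshold analysis.**  The AI surcharge enters only the cycle-0 cost
of the AI arm, so ICER(c) = (ΔC₀ + c)/ΔE and c* = target·ΔE − ΔC₀ in
closed form; a Brent root-find on the full model must agree to USD 0.01
(enforced at runtime, not just in tests).  The WTP→surcharge table is
affine with slope ΔE by construction.

**PSA.**  The distribution families are not stated in the original;
following standard practice, probabilities and utilities are sampled
from beta distributions and costs from gamma distributions,
moment-matched to the base value with a relative standard error of 10%
(configurable); boundary parameters (utility 1, verification 100%, the
draining 100% detection entry) are held fixed.  Draws violating a
validity range are redrawn and counted.  One seed spawns per-iteration
child streams (`SeedSequence.spawn`), so sample i is independent of
execution order and a shorter run reproduces the head of a longer one.
30,000 iterations run in well under a minute.  Cost-effectiveness per
iteration (and the CEAC) uses the rule "dominant, or QALY-gaining with
ICER ≤ WTP"; QALY-losing draws are never accepted, which makes the CEAC
monotone non-decreasing in WTP by construction.

## Microsimulation oracle

`synthetic.microsimulate` walks individual patients through the same
decision tree, transition matrices and accrual convention with
per-patient RNG, sharing none of the cohort algebra (no occupancy
vectors, no matrix products).  Agreement of the 200,000-patient means
with the cohort totals within 3 Monte-Carlo standard errors — for the
base case and twenty ±20% perturbed parameter sets — is the main
correctness check of the engine.  The perturbation generator
(`perturb_parameters`) scales each numeric field by U[1−w, 1+w], clamps
to validity, and keeps structure fixed (ages, horizon, final detection
probability 1).

## What the synthetic inputs do and do not emulate

Synthetic life tables reproduce the *shape* of senescent mortality, not
any official table's digits; the microsimulation shares the model's own
transition structure, so it validates the cohort arithmetic, not the
clinical realism of the model.  Passing tests therefore demonstrate
internal correctness and reproduction of the reference analysis's
structure — not that the model predicts real screening outcomes.  In
particular the model screens once (no annual repeat), has no stage
shift, no sex stratification, no Lung-RADS categories, and takes the
published "undetected cancer has utility 1 and background mortality"
literally.

## Numerical choices

Transition rows must sum to 1 within 1e−12 and per-cycle occupancy
within 1e−10 (enforced, raising on violation); the dead fraction must be
non-decreasing.  The vectorized matrix builder is asserted equal to the
scalar per-row reference implementation.  Threshold closed form vs
bisection tolerance: USD 0.01.  Ties in ICER classification: dc = dq = 0
is a "tie"; a zero-QALY increment makes the ICER undefined (`None`),
never ±∞.  Problem sizes used by the shipped tests and drivers: 20-year
horizon, 200,000 microsimulation patients, 30,000 PSA iterations.
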