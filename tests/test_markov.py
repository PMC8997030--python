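"""Markov engine: transition rows, cohort propagation, accrual conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungscreen_cea import (
    PLAIN_CONVENTION,
    REFERENCE_CONVENTION,
    State,
    accrue,
    run_cohort,
    run_strategy,
)
from lungscreen_cea.markov import (
    AccrualConvention,
    CONVENTION_GRID,
    precompute_matrices,
    transition_matrix,
    transition_row,
)
from lungscreen_cea.states import N_STATES


# ------------------------------------------------------------ rows

def test_palliative_row_is_death_or_stay(params, life_table):
    row = transition_row(State.PALLIATIVE, 70, params, life_table)
    assert row[State.DEAD] == pytest.approx(0.36)
    assert row[State.PALLIATIVE] == pytest.approx(0.64)
    assert row.sum() == pytest.approx(1.0, abs=1e-12)


def test_dead_state_is_absorbing(params, life_table):
    row = transition_row(State.DEAD, 75, params, life_table)
    assert row[State.DEAD] == 1.0
    assert row.sum() == 1.0


def test_last_undetected_year_drains_completely(params, immortal_life_table):
    """With q = 0, year-3 detection (100%) splits 26/74 resection/palliative."""
    row = transition_row(State.UNDETECTED_Y3, 65, params, immortal_life_table)
    assert row[State.AFTER_RESECTION_Y1] == pytest.approx(0.26)
    assert row[State.PALLIATIVE] == pytest.approx(0.74)
    assert row[State.UNDETECTED_Y3] == 0.0


def test_suspicious_nodule_adds_procedural_mortality(params, flat_life_table):
    row = transition_row(State.NO_BC_SUSPICIOUS, 65, params, flat_life_table)
    assert row[State.DEAD] == pytest.approx(0.02 + 0.001)
    assert row[State.NO_BC] == pytest.approx(1 - 0.021)  # verification 100%


def test_every_row_sums_to_one_at_every_age(params, life_table):
    for age in range(60, 80):
        P = transition_matrix(age, params, life_table)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)


def test_vectorized_matrices_match_scalar_reference(params, life_table):
    mats = precompute_matrices(params, life_table)
    for t in range(params.horizon_cycles):
        np.testing.assert_allclose(
            mats[t], transition_matrix(params.start_age + t, params, life_table),
            atol=1e-15,
        )


# ------------------------------------------------------------ cohort

def test_occupancy_conservation_and_monotone_death(params, ct, life_table):
    trace = run_cohort(ct, params, life_table)
    np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
    dead = trace.occupancy[:, State.DEAD]
    assert np.all(np.diff(dead) > 0)  # q > 0 at every age, so strictly increasing


def test_matrix_power_oracle(params, ct_ai, life_table):
    """Cohort propagation equals the entry row times the matrix product."""
    trace = run_cohort(ct_ai, params, life_table)
    occ = trace.occupancy[0]
    for t in range(params.horizon_cycles):
        occ = occ @ transition_matrix(params.start_age + t, params, life_table)
        np.testing.assert_allclose(trace.occupancy[t + 1], occ, atol=1e-10)


def test_immortal_undiscounted_healthy_cohort_gains_horizon_qalys(
    params, ct, immortal_life_table
):
    p = params.replace(pretest_prob=0.0, discount_rate=0.0)
    s = ct.replace(specificity=1.0)
    res = run_strategy(s, p, immortal_life_table, PLAIN_CONVENTION)
    assert res.total_qaly == pytest.approx(20.0, abs=1e-12)
    assert res.total_cost == pytest.approx(161.0, abs=1e-12)


def test_all_palliative_cohort_matches_geometric_closed_form(params, ct, life_table):
    """Palliative survival is geometric: value sums have closed forms."""
    p = params.replace(pretest_prob=1.0, p_resect_early=0.0, discount_rate=0.0)
    s = ct.replace(sensitivity=1.0)  # everyone TP, nobody resectable
    res = run_strategy(s, p, life_table, PLAIN_CONVENTION)
    expect_qaly = sum(0.63 * 0.64**t for t in range(1, 21))
    expect_cost = 161.0 + sum(60_000.0 * 0.64**t for t in range(1, 21))
    assert res.total_qaly == pytest.approx(expect_qaly, rel=1e-12)
    assert res.total_cost == pytest.approx(expect_cost, rel=1e-12)


def test_flat_mortality_survival_is_geometric(params, ct, flat_life_table):
    p = params.replace(pretest_prob=0.0)
    s = ct.replace(specificity=1.0)
    trace = run_cohort(s, p, flat_life_table)
    alive = 1.0 - trace.occupancy[:, State.DEAD]
    np.testing.assert_allclose(alive, 0.98 ** np.arange(21), atol=1e-12)


def test_discount_factor_applied_per_cycle(params, ct, immortal_life_table):
    """A fully healthy cohort accrues exactly (1+r)^-t utility in cycle t."""
    p = params.replace(pretest_prob=0.0)
    s = ct.replace(specificity=1.0)
    trace = run_cohort(s, p, immortal_life_table, PLAIN_CONVENTION)
    assert trace.qaly_per_cycle[5] == pytest.approx(1.03**-5)
    assert trace.qaly_per_cycle[0] == 0.0  # no entry-year accrual in plain convention


def test_accrue_sums_per_cycle_streams(params, ct, life_table):
    trace = run_cohort(ct, params, life_table)
    res = accrue(trace)
    assert res.total_cost == pytest.approx(trace.cost_per_cycle.sum())
    assert res.total_qaly == pytest.approx(trace.qaly_per_cycle.sum())
    assert res.strategy == "ct"


def test_fp_followup_cost_accrued_once_in_suspicious_year(params, ct, immortal_life_table):
    """A pure-FP cohort pays the work-up cost for exactly one year."""
    p = params.replace(pretest_prob=0.0, discount_rate=0.0, p_death_fp_procedural=0.0)
    s = ct.replace(specificity=0.0)  # everyone false positive
    res = run_strategy(s, p, immortal_life_table, AccrualConvention(basis="start"))
    # start-of-cycle membership: year 1 in the suspicious state, then healthy
    assert res.total_cost == pytest.approx(161.0 + 2256.0)
    assert res.total_qaly == pytest.approx(0.98 + 19.0)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    sens=st.floats(0.05, 1.0),
    bump=st.floats(0.0, 0.5),
)
def test_higher_sensitivity_never_reduces_effectiveness(
    params, ct, life_table, sens, bump
):
    """More detected cancers can only help the detecting arm's QALYs."""
    lo = ct.replace(sensitivity=min(1.0, sens))
    hi = ct.replace(sensitivity=min(1.0, sens + bump))
    q_lo = run_strategy(lo, params, life_table).total_qaly
    q_hi = run_strategy(hi, params, life_table).total_qaly
    assert q_hi >= q_lo - 1e-12


@pytest.mark.parametrize("convention", CONVENTION_GRID, ids=lambda c: c.label())
def test_invariants_hold_under_every_accrual_convention(
    params, ct_ai, life_table, convention
):
    res = run_strategy(ct_ai, params, life_table, convention)
    max_qaly = params.horizon_cycles + (1 if convention.cycle0_accrual else 0)
    assert 0.0 <= res.total_qaly <= max_qaly
    assert res.total_cost >= 0.0


def test_reference_convention_is_half_cycle_with_entry_year():
    assert REFERENCE_CONVENTION.half_cycle
    assert REFERENCE_CONVENTION.cycle0_accrual
    assert REFERENCE_CONVENTION in CONVENTION_GRID or REFERENCE_CONVENTION == next(
        c for c in CONVENTION_GRID if c.half_cycle and c.cycle0_accrual
    )
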