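"""DSA, AI-cost threshold analysis, and PSA."""

import math

import numpy as np
import pandas as pd
import pytest

from lungscreen_cea.sensitivity import (
    DistributionSpec,
    ParameterPathError,
    ThresholdError,
    apply_parameter,
    ceac,
    default_dsa_ranges,
    default_psa_specs,
    one_way,
    psa,
    resolve_parameter,
    threshold_ai_cost,
    tornado,
    wtp_cost_table,
)
from lungscreen_cea.parameters import ValidationError
from lungscreen_cea.synthetic import perturb_parameters


# ------------------------------------------------------------ paths

def test_parameter_paths_resolve_and_apply(params, strategies):
    assert resolve_parameter("pretest_prob", params, strategies) == 0.02635
    assert resolve_parameter("ct_ai.sensitivity", params, strategies) == 0.977
    assert resolve_parameter("detection_schedule[1]", params, strategies) == 0.40
    p2, s2 = apply_parameter("ct.specificity", 0.9, params, strategies)
    assert s2[0].specificity == 0.9 and p2 is params
    p3, _ = apply_parameter("p_recurrence", 0.2, params, strategies)
    assert p3.p_recurrence == 0.2


def test_unknown_path_lists_valid_paths(params, strategies):
    with pytest.raises(ParameterPathError, match="pretest_prob"):
        resolve_parameter("no_such_thing", params, strategies)


def test_out_of_range_setting_rejected(params, strategies):
    with pytest.raises(ValidationError):
        apply_parameter("p_recurrence", 1.5, params, strategies)


# ------------------------------------------------------------ one-way DSA

def test_degenerate_range_reproduces_base_case(params, strategies, life_table):
    base = resolve_parameter("p_recurrence", params, strategies)
    entry = one_way("p_recurrence", base, base, params, strategies, life_table)
    assert entry.icer_at_low == entry.icer_at_high
    assert entry.result_at_low.classification == "dominant"


def test_tornado_sorted_by_spread_and_covers_ranges(params, strategies, life_table):
    ranges = default_dsa_ranges(params, strategies, 0.2)
    assert ranges["ct.specificity"] == (pytest.approx(0.877 * 0.8), 1.0)  # clamped
    entries = tornado(params, strategies, life_table, ranges)
    assert {e.parameter for e in entries} == set(ranges)
    spreads = [e.spread for e in entries]
    assert spreads == sorted(spreads, reverse=True)


def test_dominance_robust_to_sensitivity_and_resectability(params, strategies, life_table):
    ranges = default_dsa_ranges(params, strategies, 0.2)
    for path in ("ct.sensitivity", "ct_ai.sensitivity", "p_resect_early", "p_resect_delayed"):
        e = one_way(path, *ranges[path], params, strategies, life_table)
        assert e.result_at_low.classification == "dominant", path
        assert e.result_at_high.classification == "dominant", path


# ------------------------------------------------------------ threshold

def test_threshold_closed_form_agrees_with_bisection(params, strategies, life_table):
    # the cross-check (bisection vs closed form, tolerance one cent) is
    # internal to threshold_ai_cost; a disagreement raises
    for target in (0.0, 50_000.0, 100_000.0):
        c = threshold_ai_cost(target, params, strategies, life_table, cross_check=True)
        assert c > 0


def test_threshold_cross_check_on_perturbed_models(params, strategies, life_table):
    for seed in range(6):
        p = perturb_parameters(params, 0.15, seed)
        try:
            threshold_ai_cost(100_000.0, p, strategies, life_table, cross_check=True)
        except ThresholdError:
            pass  # a perturbation may remove the effectiveness gain; that's valid


def test_threshold_error_when_no_qaly_gain(params, strategies, life_table):
    ct, ct_ai = strategies
    same = (ct, ct_ai.replace(sensitivity=ct.sensitivity, specificity=ct.specificity))
    with pytest.raises(ThresholdError, match="no finite"):
        threshold_ai_cost(0.0, params, same, life_table)


def test_wtp_cost_table_is_affine_and_monotone(params, strategies, life_table):
    wtps = [0, 20_000, 40_000, 60_000, 80_000, 100_000, 120_000, 150_000, 200_000]
    table = wtp_cost_table(wtps, params, strategies, life_table)
    costs = table["max_ai_cost"].to_numpy()
    assert np.all(np.diff(costs) > 0)
    # two points determine the line; every other point lies on it to $0.01
    slope = (costs[-1] - costs[0]) / (wtps[-1] - wtps[0])
    fitted = costs[0] + slope * (np.array(wtps) - wtps[0])
    np.testing.assert_allclose(costs, fitted, atol=0.01)
    # the slope of the line is the base-case QALY increment
    from lungscreen_cea import icer, run_strategy

    ct, ct_ai = strategies
    de = (
        run_strategy(ct_ai, params, life_table).total_qaly
        - run_strategy(ct, params, life_table).total_qaly
    )
    assert slope == pytest.approx(de, rel=1e-9)


def test_wtp_table_matches_thresholds(params, strategies, life_table):
    table = wtp_cost_table([0.0, 100_000.0], params, strategies, life_table)
    assert table["max_ai_cost"][0] == pytest.approx(
        threshold_ai_cost(0.0, params, strategies, life_table), abs=1e-9
    )


# ------------------------------------------------------------ PSA

def test_distribution_specs_validate():
    with pytest.raises(ValidationError):
        DistributionSpec("x", "lognormal", 0.5)
    with pytest.raises(ValidationError):
        DistributionSpec("x", "beta", 1.0)  # boundary mean needs 'fixed'
    with pytest.raises(ValidationError):
        DistributionSpec("x", "beta", 0.5, rel_se=2.0)  # variance too large
    with pytest.raises(ValidationError):
        DistributionSpec("x", "gamma", 0.0)


def test_beta_and_gamma_sampling_moment_match():
    rng = np.random.default_rng(0)
    spec_b = DistributionSpec("p", "beta", 0.75, rel_se=0.1)
    draws = np.array([spec_b.sample(rng) for _ in range(4000)])
    assert draws.mean() == pytest.approx(0.75, abs=0.01)
    assert draws.std() == pytest.approx(0.075, abs=0.01)
    assert np.all((draws > 0) & (draws < 1))
    spec_g = DistributionSpec("c", "gamma", 2256.0, rel_se=0.1)
    draws = np.array([spec_g.sample(rng) for _ in range(4000)])
    assert draws.mean() == pytest.approx(2256.0, rel=0.02)
    assert np.all(draws > 0)


def test_zero_variance_psa_reproduces_base_case(params, strategies, life_table):
    from lungscreen_cea import icer, run_strategy

    ct, ct_ai = strategies
    specs = [
        DistributionSpec(s.parameter, "fixed", s.mean)
        for s in default_psa_specs(params, strategies)
    ]
    result = psa(specs, 5, seed=7, params=params, strategies=strategies, lt=life_table)
    base_dc = (
        run_strategy(ct_ai, params, life_table).total_cost
        - run_strategy(ct, params, life_table).total_cost
    )
    np.testing.assert_allclose(result.samples["delta_cost"], base_dc, rtol=1e-12)
    assert result.frac_cost_effective == 1.0


def test_psa_seed_determinism(params, strategies, life_table):
    specs = default_psa_specs(params, strategies)
    a = psa(specs, 40, seed=3, params=params, strategies=strategies, lt=life_table)
    b = psa(specs, 40, seed=3, params=params, strategies=strategies, lt=life_table)
    pd.testing.assert_frame_equal(a.samples, b.samples)
    c = psa(specs, 40, seed=4, params=params, strategies=strategies, lt=life_table)
    assert not a.samples["delta_cost"].equals(c.samples["delta_cost"])


def test_dispersion_to_zero_converges_to_base_increments(params, strategies, life_table):
    from lungscreen_cea import run_strategy

    ct, ct_ai = strategies
    base_dq = (
        run_strategy(ct_ai, params, life_table).total_qaly
        - run_strategy(ct, params, life_table).total_qaly
    )
    means = []
    for rel in (0.05, 0.01, 0.002):
        specs = default_psa_specs(params, strategies, rel_se=rel)
        r = psa(specs, 60, seed=11, params=params, strategies=strategies, lt=life_table)
        means.append(r.samples["delta_qaly"].mean())
    errors = [abs(m - base_dq) for m in means]
    assert errors[2] < errors[0]
    assert errors[2] < 1e-4


def test_ceac_monotone_in_wtp(params, strategies, life_table):
    specs = default_psa_specs(params, strategies)
    r = psa(specs, 300, seed=5, params=params, strategies=strategies, lt=life_table)
    curve = ceac(r, np.linspace(0, 300_000, 16))
    probs = curve["prob_cost_effective"].to_numpy()
    assert np.all(np.diff(probs) >= 0)
    assert 0.0 <= probs[0] <= probs[-1] <= 1.0
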