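"""One-way analysis, threshold finding, PSA and acceptability curves."""

import numpy as np
import pandas as pd
import pytest

from besurv.markov import STRATEGIES
from besurv.sensitivity import (
    DistributionSpec,
    ceac,
    ce_plane,
    default_distributions,
    fraction_cost_effective,
    moment_match,
    one_way,
    run_psa,
    sample_parameter,
    threshold_find,
    tornado,
)

PAIR = (STRATEGIES["surveillance_all_LGD"], STRATEGIES["RFA_surveillance_LGD"])


# ---------------------------------------------------------------------------
# moment matching

def test_gamma_moment_match():
    assert moment_match("gamma", 100.0, 10.0) == pytest.approx(
        {"shape": 100.0, "scale": 1.0}
    )


def test_beta_moment_match():
    p = moment_match("beta", 0.9, 0.05)
    assert p["alpha"] == pytest.approx(31.5)
    assert p["beta"] == pytest.approx(3.5)


def test_zero_se_degenerates_to_mean(rng):
    d = DistributionSpec("cost_rfa", "gamma", 7000.0, 0.0)
    assert sample_parameter(d, rng) == 7000.0
    assert moment_match("beta", 0.5, 0.0) == {"degenerate": 0.5}


def test_infeasible_beta_variance_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        moment_match("beta", 0.5, 0.6)
    with pytest.raises(ValueError):
        DistributionSpec("x", "beta", 1.5, 0.1)


def test_moment_match_round_trip(rng):
    """Sampled moments reproduce the requested (mean, se)."""
    for family, mean, se in [("gamma", 1500.0, 300.0), ("beta", 0.85, 0.05)]:
        d = DistributionSpec("p", family, mean, se)
        draws = np.array([sample_parameter(d, rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(mean, rel=0.02)
        assert draws.std() == pytest.approx(se, rel=0.05)


# ---------------------------------------------------------------------------
# one-way / tornado

def test_parameter_without_effect_has_zero_swing(spec):
    """On a cohort containing only surveillance-origin LGD, the
    index-origin progression rate touches no transition either strategy
    uses, so its one-way swing is exactly zero."""
    from dataclasses import replace

    s = replace(spec, origin_mix={"surv": 1.0})
    entry = one_way(s, PAIR, "lgd_progression_rate_index")
    assert entry.icer_at_low == entry.icer_at_high
    assert entry.swing == 0.0


def test_rfa_disutility_raises_rfa_strategy_icer(spec):
    lo = one_way(spec, PAIR, "disutility_rfa", prange=(0.01, 0.2))
    assert isinstance(lo.icer_at_low, float) and isinstance(lo.icer_at_high, float)
    assert lo.icer_at_high > lo.icer_at_low


def test_one_way_midpoint_consistency(spec):
    """At a degenerate range equal to the base value the ICER equals the
    base-case ICER on both ends."""
    v = spec.params["cost_rfa"]
    entry = one_way(spec, PAIR, "cost_rfa", prange=(v, v))
    assert entry.icer_at_low == entry.icer_at_high
    assert entry.swing == 0.0


def test_one_way_clips_probability_ranges(spec):
    with pytest.warns(UserWarning, match="clipped"):
        entry = one_way(spec, PAIR, "rfa_complication_prob", prange=(-0.2, 1.5))
    assert entry.low_input == 0.0
    assert entry.high_input == 1.0


def test_tornado_sorted_by_swing(spec):
    df = tornado(spec, PAIR, parameters=["cost_rfa", "disutility_rfa", "cost_endoscopy"])
    swings = df["swing"].to_numpy()
    assert np.all(np.diff(swings[~np.isnan(swings)]) <= 0)


def test_threshold_matches_linear_closed_form(spec):
    """The RFA procedure cost enters the cost delta affinely while leaving
    QALYs untouched, so ICER(x) is an affine function of x: fit it from
    the two endpoint evaluations and solve for the λ-crossing in closed
    form, then compare with the bisection result."""
    lo_v, hi_v = 2_000.0, 40_000.0
    e = one_way(spec, PAIR, "cost_rfa", prange=(lo_v, hi_v))
    slope = (e.icer_at_high - e.icer_at_low) / (hi_v - lo_v)
    x_star = lo_v + (50_000.0 - e.icer_at_low) / slope
    res = threshold_find(spec, PAIR, "cost_rfa", wtp=50_000.0,
                         bracket=(lo_v, hi_v), tol=1e-6)
    assert res.crossing == pytest.approx(x_star, rel=1e-4)


def test_threshold_no_crossing_reported_not_raised(spec):
    res = threshold_find(spec, PAIR, "cost_rfa", wtp=1e9, bracket=(6000.0, 8000.0))
    assert res.crossing is None


def test_threshold_tolerance_contract(spec):
    coarse = threshold_find(spec, PAIR, "cost_rfa", wtp=50_000.0,
                            bracket=(2_000.0, 40_000.0), tol=10.0)
    fine = threshold_find(spec, PAIR, "cost_rfa", wtp=50_000.0,
                          bracket=(2_000.0, 40_000.0), tol=0.1)
    assert abs(fine.crossing - coarse.crossing) < 10.0


# ---------------------------------------------------------------------------
# PSA

def test_degenerate_psa_equals_deterministic(spec):
    from besurv.markov import run_strategy

    dists = [DistributionSpec(k, "fixed", v, 0.0) for k, v in spec.params.items()]
    pts = run_psa(spec, dists, n_draws=3, seed=0)
    for strat in STRATEGIES.values():
        det = run_strategy(spec, strat)
        sub = pts[pts["strategy"] == strat.name]
        assert np.allclose(sub["cost"], det.discounted_cost, atol=1e-9)
        assert np.allclose(sub["qaly"], det.discounted_qaly, atol=1e-9)


def test_psa_is_deterministic_given_seed_and_extends_streams(spec):
    dists = default_distributions(spec)
    a = run_psa(spec, dists, n_draws=8, seed=5)
    b = run_psa(spec, dists, n_draws=8, seed=5)
    pd.testing.assert_frame_equal(a, b)
    # counter-based substreams: the first draws are unchanged when n grows
    c = run_psa(spec, dists, n_draws=12, seed=5)
    pd.testing.assert_frame_equal(a, c[c["draw"] < 8].reset_index(drop=True))
    d = run_psa(spec, dists, n_draws=8, seed=6)
    assert not a.equals(d)


def test_psa_mean_near_deterministic_for_linear_inputs(spec):
    """Costs and utilities enter the accumulator linearly, so the PSA mean
    converges to the deterministic point (3 SE at n = 400)."""
    from besurv.markov import run_strategy

    dists = [
        DistributionSpec("cost_rfa", "gamma", spec.params["cost_rfa"], 1000.0),
        DistributionSpec("cost_endoscopy", "gamma", spec.params["cost_endoscopy"], 300.0),
        DistributionSpec("utility_ndbe", "beta", spec.params["utility_ndbe"], 0.02),
    ]
    pts = run_psa(spec, dists, n_draws=400, seed=2,
                  strategies=[STRATEGIES["RFA_surveillance_LGD"]])
    det = run_strategy(spec, STRATEGIES["RFA_surveillance_LGD"])
    for col, target in [("cost", det.discounted_cost), ("qaly", det.discounted_qaly)]:
        m, se = pts[col].mean(), pts[col].std() / np.sqrt(len(pts))
        assert abs(m - target) < 3 * se


def test_unknown_distribution_parameter_rejected(spec):
    with pytest.raises(KeyError, match="no_such"):
        run_psa(spec, [DistributionSpec("no_such", "gamma", 1.0, 0.1)], n_draws=1)


# ---------------------------------------------------------------------------
# CEAC

def _hand_points():
    # three draws, two strategies with known NMB orderings
    rows = []
    data = {
        "A": [(100.0, 1.0), (100.0, 1.0), (500.0, 1.0)],
        "B": [(200.0, 1.2), (50.0, 0.9), (500.0, 1.0)],
    }
    for strat, draws in data.items():
        for i, (c, q) in enumerate(draws):
            rows.append((i, strat, c, q, 0.0))
    return pd.DataFrame(rows, columns=["draw", "strategy", "cost", "qaly",
                                       "eac_incidence"])


def test_ceac_by_direct_enumeration():
    pts = _hand_points()
    curves = ceac(pts, np.array([0.0, 1000.0]))
    # λ=0: cheapest wins each draw; draw 2 ties and splits
    assert curves.loc[0.0, "A"] == pytest.approx((1 + 0 + 0.5) / 3)
    assert curves.loc[0.0, "B"] == pytest.approx((0 + 1 + 0.5) / 3)
    # λ=1000: draw 0 -> B (NMB 1000 vs 900); draw 1 -> B (850 vs 900)? no:
    # A: 1*1000-100=900, B: 0.9*1000-50=850 -> A; draw 2 ties again
    assert curves.loc[1000.0, "B"] == pytest.approx((1 + 0 + 0.5) / 3)


def test_ceac_fractions_sum_to_one(spec):
    pts = run_psa(spec, default_distributions(spec), n_draws=25, seed=9)
    curves = ceac(pts, np.arange(0, 100_001, 10_000, dtype=float))
    assert np.allclose(curves.sum(axis=1), 1.0, atol=1e-12)
    assert ((curves >= 0) & (curves <= 1)).all().all()


def test_single_strategy_ceac_is_one_everywhere(spec):
    pts = run_psa(spec, default_distributions(spec), n_draws=5, seed=1,
                  strategies=[STRATEGIES["surveillance_all_LGD"]])
    curves = ceac(pts, np.array([0.0, 5e4, 1e5]))
    assert np.allclose(curves.to_numpy(), 1.0)


def test_ce_plane_and_fraction_cost_effective(spec):
    pts = run_psa(spec, default_distributions(spec), n_draws=30, seed=4)
    plane = ce_plane(pts, "surveillance_all_LGD")
    assert set(plane["strategy"]) == set(STRATEGIES) - {"surveillance_all_LGD"}
    frac = fraction_cost_effective(pts, "surveillance_all_LGD",
                                   "RFA_surveillance_LGD", 50_000.0)
    assert 0.0 <= frac <= 1.0
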