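"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs a pair of strategies while sweeping a single
input across a range (default mean ± 2·SE, clipped to validity),
recording the ICER swing for a tornado diagram, with bisection-based
threshold finding against the willingness-to-pay. Probabilistic analysis
draws all uncertain inputs at once — gamma for costs, beta for
probabilities and utilities, parameterised by method of moments from
(mean, SE) — re-runs every strategy per draw, and summarises the draws
as a cost-effectiveness plane and acceptability curves.

Randomness uses one top-level seed with a counter-based substream per
draw, so draw ``i`` is identical whether 100 or 5000 draws are requested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .econ import StrategyResult, icer, nmb
from .markov import STRATEGIES, ModelSpec, Strategy, run_strategy

#: parameters that must stay within [0, 1]
_UNIT_INTERVAL_HINTS = ("prob", "utility", "disutility", "frac_")


def _is_unit_interval(name: str) -> bool:
    return any(h in name for h in _UNIT_INTERVAL_HINTS)


@dataclass(frozen=True)
class DistributionSpec:
    """Second-moment description of one uncertain input.

    ``family`` is ``gamma`` (costs and rates), ``beta`` (probabilities
    and utilities) or ``fixed``; ``se = 0`` degenerates any family to a
    point mass at the mean.
    """

    parameter_name: str
    family: str
    mean: float
    se: float
    low: float | None = None   # optional one-way range override
    high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "beta", "fixed"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.family == "beta" and not 0 < self.mean < 1:
            raise ValueError("beta mean must lie in (0, 1)")
        if self.family == "gamma" and self.mean <= 0:
            raise ValueError("gamma mean must be positive")


def moment_match(family: str, mean: float, se: float) -> dict[str, float]:
    """Method-of-moments hyper-parameters for a gamma or beta distribution.

    gamma: shape = mean²/se², scale = se²/mean.
    beta:  ν = mean(1−mean)/se² − 1, α = mean·ν, β = (1−mean)·ν; the
    variance must satisfy se² < mean(1−mean).
    """
    if se == 0:
        return {"degenerate": mean}
    if family == "gamma":
        if mean <= 0:
            raise ValueError("gamma mean must be positive")
        return {"shape": mean**2 / se**2, "scale": se**2 / mean}
    if family == "beta":
        if not 0 < mean < 1:
            raise ValueError("beta mean must lie in (0, 1)")
        if se**2 >= mean * (1 - mean):
            raise ValueError(
                f"beta variance {se**2:.4g} infeasible for mean {mean} "
                f"(needs < {mean * (1 - mean):.4g})"
            )
        nu = mean * (1 - mean) / se**2 - 1
        return {"alpha": mean * nu, "beta": (1 - mean) * nu}
    if family == "fixed":
        return {"degenerate": mean}
    raise ValueError(f"unknown family {family!r}")


def sample_parameter(dist: DistributionSpec, rng: np.random.Generator) -> float:
    if dist.se == 0 or dist.family == "fixed":
        return dist.mean
    p = moment_match(dist.family, dist.mean, dist.se)
    if dist.family == "gamma":
        return float(rng.gamma(p["shape"], p["scale"]))
    return float(rng.beta(p["alpha"], p["beta"]))


def default_distributions(spec: ModelSpec, rel_se: float = 0.2) -> list[DistributionSpec]:
    """A PSA specification covering every cost, probability, utility and
    rate input: gamma for costs and rates, beta for unit-interval
    quantities, each with SE equal to ``rel_se`` of the mean (capped for
    beta feasibility)."""
    dists = []
    for name, value in spec.params.items():
        if value == 0:
            dists.append(DistributionSpec(name, "fixed", value, 0.0))
        elif _is_unit_interval(name):
            se = min(rel_se * value, 0.9 * math.sqrt(value * (1 - value)))
            dists.append(DistributionSpec(name, "beta", value, se))
        else:
            dists.append(DistributionSpec(name, "gamma", value, rel_se * value))
    return dists


# ---------------------------------------------------------------------------
# one-way (deterministic) analysis

@dataclass(frozen=True)
class TornadoEntry:
    parameter_name: str
    low_input: float
    high_input: float
    icer_at_low: float | str
    icer_at_high: float | str
    swing: float


def _pair_icer(spec: ModelSpec, pair: tuple[Strategy, Strategy]) -> float | str:
    base, comp = pair
    rb = run_strategy(spec, base)
    rc = run_strategy(spec, comp)
    return icer(rc.discounted_cost - rb.discounted_cost,
                rc.discounted_qaly - rb.discounted_qaly)


def _icer_magnitude(v: float | str) -> float:
    """Numeric stand-in for swing computation; dominance labels map to nan."""
    return v if isinstance(v, (int, float)) else float("nan")


def clip_range(name: str, low: float, high: float) -> tuple[float, float]:
    lo, hi = low, high
    if _is_unit_interval(name):
        lo2, hi2 = max(lo, 0.0), min(hi, 1.0)
    else:
        lo2, hi2 = max(lo, 0.0), hi
    if (lo2, hi2) != (lo, hi):
        warnings.warn(f"one-way range for {name} clipped to [{lo2}, {hi2}]",
                      stacklevel=2)
    return lo2, hi2


def one_way(
    spec: ModelSpec,
    strategy_pair: tuple[Strategy, Strategy],
    parameter: str,
    prange: tuple[float, float] | None = None,
    n_points: int = 2,
) -> TornadoEntry:
    """ICER of ``comparator vs base`` at the ends of a one-way range.

    The default range is mean ± 2·(0.2·mean), clipped to validity. The
    swing is |ICER(high) − ICER(low)| and is nan if either end is a
    dominance label.
    """
    if parameter not in spec.params:
        raise KeyError(f"unknown parameter {parameter!r}")
    base_value = spec.params[parameter]
    if prange is None:
        prange = (base_value * 0.6, base_value * 1.4)  # mean ± 2 × 20% SE
    lo, hi = clip_range(parameter, *prange)
    grid = np.linspace(lo, hi, max(2, n_points))
    icers = [_pair_icer(spec.with_params(**{parameter: float(v)}), strategy_pair)
             for v in grid]
    i_lo, i_hi = icers[0], icers[-1]
    swing = abs(_icer_magnitude(i_hi) - _icer_magnitude(i_lo))
    return TornadoEntry(parameter, float(grid[0]), float(grid[-1]), i_lo, i_hi, swing)


def tornado(
    spec: ModelSpec,
    strategy_pair: tuple[Strategy, Strategy],
    parameters: list[str] | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """One-way analysis over many parameters, sorted by descending swing."""
    parameters = parameters or [k for k, v in spec.params.items() if v != 0]
    ranges = ranges or {}
    entries = [one_way(spec, strategy_pair, p, ranges.get(p)) for p in parameters]
    df = pd.DataFrame([e.__dict__ for e in entries])
    return df.sort_values("swing", ascending=False, ignore_index=True)


@dataclass(frozen=True)
class ThresholdResult:
    parameter_name: str
    crossing: float | None    # None when the ICER never crosses wtp
    icer_at_low: float | str
    icer_at_high: float | str


def threshold_find(
    spec: ModelSpec,
    strategy_pair: tuple[Strategy, Strategy],
    parameter: str,
    wtp: float | None = None,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-4,
) -> ThresholdResult:
    """Parameter value at which the pairwise ICER crosses willingness-to-pay.

    Bisection (Brent) on ICER(x) − λ over the bracket; requires the ICER
    to be monotone over the bracket. Absence of a sign change is reported
    as ``crossing=None``, not raised.
    """
    wtp = spec.wtp if wtp is None else wtp
    if bracket is None:
        v = spec.params[parameter]
        bracket = clip_range(parameter, v * 0.6, v * 1.4)
    lo, hi = bracket

    def f(x: float) -> float:
        v = _pair_icer(spec.with_params(**{parameter: float(x)}), strategy_pair)
        return _icer_magnitude(v) - wtp

    f_lo, f_hi = f(lo), f(hi)
    ic_lo, ic_hi = f_lo + wtp, f_hi + wtp
    if math.isnan(f_lo) or math.isnan(f_hi) or f_lo * f_hi > 0:
        return ThresholdResult(parameter, None, ic_lo, ic_hi)
    x = optimize.brentq(f, lo, hi, xtol=tol)
    return ThresholdResult(parameter, float(x), ic_lo, ic_hi)


# ---------------------------------------------------------------------------
# probabilistic analysis

def run_psa(
    spec: ModelSpec,
    distribution_specs: list[DistributionSpec] | None = None,
    n_draws: int = 5000,
    seed: int = 0,
    strategies: list[Strategy] | None = None,
) -> pd.DataFrame:
    """Monte Carlo over parameter uncertainty.

    Per draw, every distributed input is sampled (independently), the
    model is rebuilt, and all strategies are run. Returns a long
    DataFrame with columns ``draw, strategy, cost, qaly, eac_incidence``.
    Transition rows that a draw pushes past total probability 1 are
    renormalised inside the engine (the audit mechanism of the matrix
    builder), never rejected, so every draw produces a point.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    spec.validate()
    dists = distribution_specs if distribution_specs is not None else default_distributions(spec)
    strategies = strategies or list(STRATEGIES.values())
    unknown = [d.parameter_name for d in dists if d.parameter_name not in spec.params]
    if unknown:
        raise KeyError(f"distributions reference unknown parameters {unknown}")
    rows = []
    for i in range(n_draws):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        draws = {d.parameter_name: sample_parameter(d, rng) for d in dists}
        s = spec.with_params(**draws)
        for strat in strategies:
            r = run_strategy(s, strat)
            rows.append((i, strat.name, r.discounted_cost, r.discounted_qaly,
                         r.cumulative_eac_incidence))
    return pd.DataFrame(rows, columns=["draw", "strategy", "cost", "qaly",
                                       "eac_incidence"])


def ce_plane(points: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Incremental cost/QALY of each strategy vs the baseline, per draw."""
    wide_c = points.pivot(index="draw", columns="strategy", values="cost")
    wide_q = points.pivot(index="draw", columns="strategy", values="qaly")
    if baseline not in wide_c.columns:
        raise ValueError(f"baseline {baseline!r} absent from PSA points")
    rows = []
    for strat in wide_c.columns:
        if strat == baseline:
            continue
        rows.append(
            pd.DataFrame(
                {
                    "draw": wide_c.index,
                    "strategy": strat,
                    "delta_cost": wide_c[strat] - wide_c[baseline],
                    "delta_qaly": wide_q[strat] - wide_q[baseline],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def fraction_cost_effective(
    points: pd.DataFrame, baseline: str, strategy: str, wtp: float
) -> float:
    """Fraction of draws in which ``strategy`` beats the baseline at λ
    (incremental NMB > 0); ties count half."""
    plane = ce_plane(points, baseline)
    sub = plane.loc[plane["strategy"] == strategy]
    inb = sub["delta_qaly"] * wtp - sub["delta_cost"]
    return float(((inb > 0).sum() + 0.5 * (inb == 0).sum()) / len(sub))


def ceac(
    points: pd.DataFrame, wtp_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    Per λ and per draw the strategy with maximal NMB wins; exact NMB ties
    split the win equally among the tied strategies. Returns a DataFrame
    indexed by ``wtp`` with one win-fraction column per strategy
    (rows sum to 1).
    """
    if points.empty:
        raise ValueError("no PSA draws provided")
    if wtp_grid is None:
        wtp_grid = np.arange(0, 100_001, 1000, dtype=float)
    wide_c = points.pivot(index="draw", columns="strategy", values="cost").to_numpy()
    wide_q = points.pivot(index="draw", columns="strategy", values="qaly").to_numpy()
    strategies = list(points.pivot(index="draw", columns="strategy", values="cost").columns)
    n_draws = wide_c.shape[0]
    out = np.zeros((len(wtp_grid), len(strategies)))
    for j, lam in enumerate(wtp_grid):
        benefit = wide_q * lam - wide_c
        best = benefit.max(axis=1, keepdims=True)
        winners = np.isclose(benefit, best, rtol=0.0, atol=1e-9)
        out[j] = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0) / n_draws
    return pd.DataFrame(out, index=pd.Index(wtp_grid, name="wtp"), columns=strategies)
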