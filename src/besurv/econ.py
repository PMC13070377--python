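"""Strategy comparison: ICERs, net monetary benefit, efficiency frontier.

Comparisons can be reported two ways: every strategy against the common
baseline (the presentation used for surveillance-vs-ablation tables), or
sequentially along the efficiency frontier after removing dominated and
extendedly dominated strategies. Baseline mode is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .markov import STRATEGIES, ModelSpec, Strategy, run_strategy

# dominance labels returned instead of a numeric ICER
DOMINATED = "dominated"
DOMINANT = "dominant"            # cost-saving and at least as effective
EQUIVALENT = "equivalent"
EXTENDEDLY_DOMINATED = "extendedly_dominated"
REFERENCE = "reference"


@dataclass(frozen=True)
class StrategyResult:
    strategy_name: str
    cost: float
    qaly: float
    eac_incidence: float = float("nan")

    def __post_init__(self) -> None:
        if self.cost < 0 or self.qaly < 0:
            raise ValueError("cost and QALY must be non-negative")


@dataclass(frozen=True)
class FrontierEntry:
    strategy_name: str
    delta_cost: float
    delta_qaly: float
    icer: float | str
    nmb: float
    cost_effective: bool = False


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost-effectiveness ratio, or a dominance label.

    More effective and more costly → Δcost/ΔQALY; less (or equally)
    effective and more costly → ``dominated``; at least as effective and
    no more costly → ``dominant``; no difference at all → ``equivalent``.
    """
    if delta_qaly == 0 and delta_cost == 0:
        return EQUIVALENT
    if delta_qaly > 0:
        return DOMINANT if delta_cost <= 0 else delta_cost / delta_qaly
    return DOMINATED if delta_cost >= 0 else delta_cost / delta_qaly


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit QALY·λ − cost at willingness-to-pay λ."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return qaly * wtp - cost


def evaluate_strategies(
    spec: ModelSpec, strategies: list[Strategy] | None = None
) -> list[StrategyResult]:
    """Run the cohort model for each strategy and collect its outcomes."""
    strategies = strategies or list(STRATEGIES.values())
    out = []
    for s in strategies:
        r = run_strategy(spec, s)
        out.append(
            StrategyResult(s.name, r.discounted_cost, r.discounted_qaly,
                           r.cumulative_eac_incidence)
        )
    return out


def compare_to_baseline(
    results: list[StrategyResult], baseline: str, wtp: float
) -> pd.DataFrame:
    """Pairwise comparison of every strategy against one baseline.

    Columns: ``strategy, cost, qaly, eac_incidence, delta_cost,
    delta_qaly, icer, nmb``; the baseline row carries the ``reference``
    label.
    """
    names = [r.strategy_name for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    if baseline not in names:
        raise ValueError(f"baseline {baseline!r} not among results")
    base = next(r for r in results if r.strategy_name == baseline)
    rows = []
    for r in results:
        if r.strategy_name == baseline:
            dc, dq, ic = 0.0, 0.0, REFERENCE
        else:
            dc, dq = r.cost - base.cost, r.qaly - base.qaly
            ic = icer(dc, dq)
        rows.append(
            dict(strategy=r.strategy_name, cost=r.cost, qaly=r.qaly,
                 eac_incidence=r.eac_incidence, delta_cost=dc, delta_qaly=dq,
                 icer=ic, nmb=nmb(r.cost, r.qaly, wtp))
        )
    return pd.DataFrame(rows)


def efficiency_frontier(
    results: list[StrategyResult], wtp: float
) -> list[FrontierEntry]:
    """Efficient-frontier analysis with sequential ICERs.

    Strategies are sorted by cost; any strategy no more effective than a
    cheaper one is dominated; strategies whose sequential ICER exceeds
    that of the next frontier step are extendedly dominated (a mixture of
    neighbours beats them). Frontier entries report the ICER against the
    previous frontier strategy, and the strategy with the highest NMB at
    ``wtp`` is flagged cost-effective.
    """
    names = [r.strategy_name for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    if len(results) < 2:
        raise ValueError("need at least two strategies")
    order = sorted(results, key=lambda r: (r.cost, -r.qaly))
    status: dict[str, str] = {}
    # strict dominance: a cheaper-or-equal strategy with >= QALYs exists
    for i, r in enumerate(order):
        for s in order[:i]:
            if s.qaly >= r.qaly:
                status[r.strategy_name] = DOMINATED
                break
    frontier = [r for r in order if r.strategy_name not in status]
    # extended dominance: enforce increasing sequential ICERs
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            a, b, c = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_ab = (b.cost - a.cost) / (b.qaly - a.qaly)
            icer_bc = (c.cost - b.cost) / (c.qaly - b.qaly)
            if icer_ab >= icer_bc:
                status[b.strategy_name] = EXTENDEDLY_DOMINATED
                frontier.pop(i)
                changed = True
                break
    best = max(frontier, key=lambda r: nmb(r.cost, r.qaly, wtp))
    entries = []
    prev = None
    for r in order:
        label = status.get(r.strategy_name)
        if label is not None:
            ic: float | str = label
            dc = dq = float("nan")
        elif prev is None:
            ic, dc, dq = REFERENCE, 0.0, 0.0
            prev = r
        else:
            dc, dq = r.cost - prev.cost, r.qaly - prev.qaly
            ic = icer(dc, dq)
            prev = r
        entries.append(
            FrontierEntry(
                strategy_name=r.strategy_name,
                delta_cost=dc,
                delta_qaly=dq,
                icer=ic,
                nmb=nmb(r.cost, r.qaly, wtp),
                cost_effective=r.strategy_name == best.strategy_name,
            )
        )
    return entries


def frontier_table(entries: list[FrontierEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])
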