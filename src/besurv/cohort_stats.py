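"""Person-time progression statistics for a Barrett's esophagus surveillance cohort.

Crude progression proportions, incidence rates per 100 person-years with
exact (Garwood) Poisson confidence intervals, and incidence rate ratios
with exact conditional (binomial) confidence intervals.

The exact methods are used because progression events are rare (tens of
events over thousands of person-years); normal approximations are
unreliable at these counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats


class Group(str, Enum):
    """Surveillance cohort groups by dysplasia history."""

    ND = "ND"                  # non-dysplastic Barrett's throughout
    LGD_ENTRY = "LGD_entry"    # low-grade dysplasia at the index endoscopy
    LGD_SURV = "LGD_surv"      # LGD developing during surveillance


#: Canonical group ordering used in all tabular output.
GROUP_ORDER: tuple[Group, ...] = (Group.ND, Group.LGD_ENTRY, Group.LGD_SURV)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching clinical-report conventions.

    Python's builtin ``round`` uses banker's rounding, which turns 15.55 %
    into 15.5 % rather than the 15.6 % a report would print.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GroupCounts:
    """Event and exposure totals for one cohort group."""

    group_label: Group
    n_patients: int
    n_events: int
    person_years: float

    def __post_init__(self) -> None:
        if self.n_events < 0 or self.n_patients < 0:
            raise ValueError("counts must be non-negative")
        if self.n_events > self.n_patients:
            raise ValueError(
                f"n_events ({self.n_events}) exceeds n_patients ({self.n_patients})"
            )
        if self.n_patients > 0 and self.person_years <= 0:
            raise ValueError("person_years must be positive when patients are present")


@dataclass(frozen=True)
class RateEstimate:
    """Incidence rate per 100 person-years with an exact Poisson CI."""

    rate_per_100py: float
    ci_low: float
    ci_high: float
    events: int
    person_years: float
    alpha: float = 0.05

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(self.rate_per_100py, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )


@dataclass(frozen=True)
class IRREstimate:
    """Incidence rate ratio against a reference group, exact conditional CI.

    ``ci_high`` is ``inf`` when the reference group has zero events; this is
    flagged via ``unbounded_upper`` rather than raised as an error.
    """

    irr: float
    ci_low: float
    ci_high: float
    reference_group: Group
    alpha: float = 0.05

    @property
    def unbounded_upper(self) -> bool:
        return math.isinf(self.ci_high)

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(self.irr, ndigits),
            round_half_up(self.ci_low, ndigits),
            self.ci_high if math.isinf(self.ci_high) else round_half_up(self.ci_high, ndigits),
        )


def crude_proportion(events: int, n: int) -> float:
    """Crude progression percentage, rounded half-up to one decimal.

    Parameters
    ----------
    events : number of patients who progressed.
    n : number of patients at risk.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if events < 0 or events > n:
        raise ValueError("events must lie in [0, n]")
    return round_half_up(100.0 * events / n, 1)


def person_time_rate(events: int, person_years: float, alpha: float = 0.05) -> RateEstimate:
    """Incidence rate per 100 person-years with the exact Garwood Poisson CI.

    The bounds come from the chi-square representation of the Poisson
    count distribution: for k observed events the lower bound is
    ``chi2.ppf(alpha/2, 2k)/2`` and the upper ``chi2.ppf(1-alpha/2, 2k+2)/2``,
    both scaled by ``100/person_years``; the lower bound is zero when k = 0.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    scale = 100.0 / person_years
    low = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2 * scale
    high = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2 * scale
    return RateEstimate(
        rate_per_100py=events * scale,
        ci_low=low,
        ci_high=high,
        events=events,
        person_years=person_years,
        alpha=alpha,
    )


def incidence_rate_ratio(g1: GroupCounts, g0: GroupCounts, alpha: float = 0.05) -> IRREstimate:
    """Incidence rate ratio of ``g1`` against reference ``g0``.

    The CI is the exact conditional interval: conditional on the total
    event count ``k1 + k0``, ``k1`` is binomial with success probability
    ``p = IRR·PY1 / (IRR·PY1 + PY0)``. A Clopper–Pearson interval for
    ``p`` is transformed back through ``IRR = p/(1-p) · PY0/PY1``. Zero
    events in the reference group make the upper bound infinite, which is
    reported (``unbounded_upper``) rather than raised.
    """
    if g1.person_years <= 0 or g0.person_years <= 0:
        raise ValueError("both groups need positive person-years")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k1, k0 = g1.n_events, g0.n_events
    n = k1 + k0
    f = g0.person_years / g1.person_years
    irr = math.inf if k0 == 0 and k1 > 0 else (k1 / g1.person_years) / (k0 / g0.person_years) if k0 > 0 else float("nan")
    if n == 0:
        # no events anywhere: ratio undefined, interval maximally wide
        return IRREstimate(float("nan"), 0.0, math.inf, g0.group_label, alpha)
    p_low = stats.beta.ppf(alpha / 2, k1, n - k1 + 1) if k1 > 0 else 0.0
    p_high = stats.beta.ppf(1 - alpha / 2, k1 + 1, n - k1) if k1 < n else 1.0
    lo = p_low / (1 - p_low) * f
    hi = math.inf if p_high >= 1 else p_high / (1 - p_high) * f
    return IRREstimate(irr=irr, ci_low=lo, ci_high=hi, reference_group=g0.group_label, alpha=alpha)


REQUIRED_COLUMNS = ("patient_id", "group", "person_years", "event", "event_type")


def _validate_cohort(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    labels = {g.value for g in Group}
    bad = table.loc[~table["group"].isin(labels)]
    if not bad.empty:
        rows = bad.index.tolist()[:10]
        raise ValueError(
            f"unknown group labels {sorted(bad['group'].unique())} in rows {rows}; "
            f"expected one of {sorted(labels)}"
        )


def cohort_summary(table: pd.DataFrame) -> list[GroupCounts]:
    """Aggregate a patient-level cohort table into per-group event/exposure totals.

    Returns one :class:`GroupCounts` per group present (in canonical order);
    pooled totals are obtained with :func:`pooled_counts`.
    """
    if table.empty:
        return []
    _validate_cohort(table)
    out: list[GroupCounts] = []
    for g in GROUP_ORDER:
        sub = table.loc[table["group"] == g.value]
        if sub.empty:
            continue
        out.append(
            GroupCounts(
                group_label=g,
                n_patients=len(sub),
                n_events=int(sub["event"].sum()),
                person_years=float(sub["person_years"].sum()),
            )
        )
    return out


def pooled_counts(groups: Sequence[GroupCounts]) -> GroupCounts:
    """Pool group totals. Printed reports may round per-group person-years,
    so a pooled figure can differ from the sum of rounded parts."""
    if not groups:
        raise ValueError("nothing to pool")
    return GroupCounts(
        group_label=groups[0].group_label,  # label is not meaningful for the pool
        n_patients=sum(g.n_patients for g in groups),
        n_events=sum(g.n_events for g in groups),
        person_years=sum(g.person_years for g in groups),
    )


def rates_table(
    groups: Iterable[GroupCounts],
    alpha: float = 0.05,
    reference: Group = Group.ND,
) -> pd.DataFrame:
    """Full rates report: per-group rates with exact CIs plus IRRs against
    the reference group, and a pooled row.

    Columns: ``group, n, events, person_years, rate_per_100py, ci_low,
    ci_high, irr, irr_low, irr_high`` (unrounded; use
    :func:`render_report` for the 1-decimal presentation).
    """
    groups = list(groups)
    by_label = {g.group_label: g for g in groups}
    if reference not in by_label:
        raise ValueError(f"reference group {reference} absent from summary")
    ref = by_label[reference]
    rows = []
    for g in groups:
        r = person_time_rate(g.n_events, g.person_years, alpha)
        if g.group_label == reference:
            irr, lo, hi = 1.0, float("nan"), float("nan")
        else:
            e = incidence_rate_ratio(g, ref, alpha)
            irr, lo, hi = e.irr, e.ci_low, e.ci_high
        rows.append(
            dict(
                group=g.group_label.value,
                n=g.n_patients,
                events=g.n_events,
                person_years=g.person_years,
                rate_per_100py=r.rate_per_100py,
                ci_low=r.ci_low,
                ci_high=r.ci_high,
                irr=irr,
                irr_low=lo,
                irr_high=hi,
            )
        )
    pool = pooled_counts(groups)
    rp = person_time_rate(pool.n_events, pool.person_years, alpha)
    rows.append(
        dict(
            group="all",
            n=pool.n_patients,
            events=pool.n_events,
            person_years=pool.person_years,
            rate_per_100py=rp.rate_per_100py,
            ci_low=rp.ci_low,
            ci_high=rp.ci_high,
            irr=float("nan"),
            irr_low=float("nan"),
            irr_high=float("nan"),
        )
    )
    return pd.DataFrame(rows)


def render_report(table: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Presentation copy of a rates table with half-up rounding applied."""
    out = table.copy()
    for col in ("rate_per_100py", "ci_low", "ci_high", "irr", "irr_low", "irr_high"):
        out[col] = [
            round_half_up(v, ndigits) if pd.notna(v) and math.isfinite(v) else v
            for v in out[col]
        ]
    out["person_years"] = [round_half_up(v, 0) for v in out["person_years"]]
    return out
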