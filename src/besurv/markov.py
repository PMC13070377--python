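"""Discrete-time Markov cohort engine for Barrett's esophagus management.

The model follows a cohort of patients with low-grade dysplasia (LGD)
through half-year cycles over a 35-year horizon. Health states cover
non-dysplastic Barrett's under lengthening surveillance intervals
(6 / 12 / 24 months, encoded as tunnel states), LGD, high-grade dysplasia
(HGD), early (T1a) and advanced esophageal adenocarcinoma (EAC),
post-ablation states, and cancer / other-cause death. Costs and
quality-adjusted life years accrue per cycle on state occupancy and per
event on transition flow, discounted at an annual rate.

Two LGD origins are distinguished — LGD present at the index endoscopy
versus LGD arising during surveillance — because they progress at
different observed rates and because the ablation strategies under
comparison trigger on exactly this distinction. The engine runs each
origin as its own subcohort (all starting in LGD) and mixes outcomes by
the base-case origin split, which is equivalent to carrying origin-tagged
state copies but keeps matrices small.

Four management strategies are compared: surveillance for all LGD
(ablation only at HGD/EAC), ablation of index LGD only, ablation of
surveillance-detected LGD only, and ablation of all LGD. All strategies
ablate HGD with radiofrequency ablation (RFA) and resect early cancer
(EMR then RFA); advanced cancer receives stage-appropriate oncology care
modelled as a payoff bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

ORIGINS = ("index", "surv")


@dataclass(frozen=True)
class HealthState:
    name: str
    absorbing: bool = False
    accrues_utility: bool = True


#: Canonical state set. Order is load-bearing: matrices and traces use it.
STATES: tuple[HealthState, ...] = (
    HealthState("NDBE_surv6m"),
    HealthState("NDBE_surv12m"),
    HealthState("NDBE_surv24m"),
    HealthState("LGD"),
    HealthState("HGD"),
    HealthState("EAC_T1a"),
    HealthState("EAC_advanced"),
    HealthState("post_RFA"),
    HealthState("post_EMR_RFA"),
    HealthState("cancer_death", absorbing=True, accrues_utility=False),
    HealthState("other_death", absorbing=True, accrues_utility=False),
)

STATE_NAMES = tuple(s.name for s in STATES)
IDX = {s.name: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

#: States counted when measuring cumulative EAC incidence (first entry only;
#: recurrence flowing out of post_EMR_RFA is not a new incident cancer).
EAC_STATES = ("EAC_T1a", "EAC_advanced")
EAC_RECURRENCE_SOURCES = ("EAC_T1a", "EAC_advanced", "post_EMR_RFA")


@dataclass(frozen=True)
class Strategy:
    """One of the four management strategies.

    ``ablate_origins`` names the LGD origins whose LGD state is routed
    straight to RFA; HGD and EAC handling is identical across strategies.
    """

    name: str
    ablate_origins: frozenset[str] = frozenset()

    def ablates(self, origin: str) -> bool:
        return origin in self.ablate_origins


STRATEGIES: dict[str, Strategy] = {
    "surveillance_all_LGD": Strategy("surveillance_all_LGD"),
    "RFA_index_LGD": Strategy("RFA_index_LGD", frozenset({"index"})),
    "RFA_surveillance_LGD": Strategy("RFA_surveillance_LGD", frozenset({"surv"})),
    "RFA_all_LGD": Strategy("RFA_all_LGD", frozenset({"index", "surv"})),
}


@dataclass
class ModelSpec:
    """Complete model configuration: grid, discounting, and named parameters.

    ``params`` carries annual rates, per-cycle detection probabilities,
    costs (AUD) and annual utilities under flat names so that sensitivity
    analyses can perturb any input uniformly. ``provenance`` tags each
    parameter as study-calibrated, study-observed or a documented
    placeholder awaiting source values.
    """

    params: dict[str, float]
    cycle_length: float = 0.5
    horizon: float = 35.0
    discount_rate_annual: float = 0.05
    wtp: float = 50_000.0
    origin_mix: dict[str, float] = field(
        default_factory=lambda: {"index": 0.52, "surv": 0.48}
    )
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        n = self.horizon / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ValueError("horizon must be a whole number of cycles")
        return int(round(n))

    def validate(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.discount_rate_annual <= -1:
            raise ValueError("discount rate must exceed -100%")
        if abs(sum(self.origin_mix.values()) - 1.0) > 1e-9:
            raise ValueError("origin_mix must sum to 1")
        if set(self.origin_mix) - set(ORIGINS):
            raise ValueError(f"unknown origins {set(self.origin_mix) - set(ORIGINS)}")
        self.n_cycles  # raises if not integral
        for k, v in self.params.items():
            if (k.startswith("p_") or k.endswith("_prob") or "_prob_" in k) and not 0 <= v <= 1:
                raise ValueError(f"parameter {k}={v} is not a probability")

    def with_params(self, **updates: float) -> "ModelSpec":
        unknown = set(updates) - set(self.params)
        if unknown:
            raise KeyError(f"unknown parameters {sorted(unknown)}")
        return replace(self, params={**self.params, **updates})


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions, one row per cycle boundary."""

    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    state_names: tuple[str, ...] = STATE_NAMES

    def __post_init__(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"occupancy row {bad} sums to {sums[bad]!r}, not 1")

    def column(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.state_names.index(state)]


@dataclass(frozen=True)
class EconOutcome:
    """Discounted and undiscounted cost/QALY totals plus cancer incidence."""

    discounted_cost: float
    discounted_qaly: float
    cumulative_eac_incidence: float
    undiscounted_cost: float
    undiscounted_qaly: float


# ---------------------------------------------------------------------------
# elementary conversions

def rate_to_probability(annual_rate: float, cycle_length: float) -> float:
    """Constant-hazard conversion of an annual rate to a per-cycle probability."""
    if annual_rate < 0:
        raise ValueError("rate must be non-negative")
    return -math.expm1(-annual_rate * cycle_length)


def probability_to_rate(p: float, cycle_length: float) -> float:
    """Inverse of :func:`rate_to_probability`."""
    if not 0 <= p < 1:
        raise ValueError("probability must lie in [0, 1)")
    return -math.log1p(-p) / cycle_length


def discount_factor(cycle_index: int, annual_rate: float, cycle_length: float) -> float:
    """Discrete per-cycle discount factor (1 + r)^(-t·Δ)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    if annual_rate <= -1:
        raise ValueError("discount rate must exceed -100%")
    return (1.0 + annual_rate) ** (-cycle_index * cycle_length)


# ---------------------------------------------------------------------------
# matrix construction

def _set_row(P: np.ndarray, row: str, flows: dict[str, float],
             stay: str, audit: list[str]) -> None:
    """Fill one transition row: named outflows, remainder to ``stay``.

    Competing per-cycle probabilities can overshoot 1 under extreme
    sensitivity draws; the row is then rescaled to sum to 1 and the
    rescaling recorded in ``audit`` rather than failing silently.
    """
    i = IDX[row]
    total = sum(flows.values())
    if total > 1.0:
        scale = 1.0 / total
        flows = {k: v * scale for k, v in flows.items()}
        audit.append(f"row {row}: outflows summed to {total:.6f}, rescaled")
        total = 1.0
    for name, p in flows.items():
        if p < 0:
            raise ValueError(f"negative probability {p} for {row}->{name}")
        P[i, IDX[name]] += p
    P[i, IDX[stay]] += 1.0 - total


def apply_strategy_rewiring(
    spec: ModelSpec, strategy: Strategy, origin: str
) -> tuple[np.ndarray, list[str]]:
    """Build the per-cycle transition matrix for one LGD origin under a strategy.

    Only the LGD row differs across strategies: when the strategy ablates
    this origin's LGD, the row routes to ``post_RFA`` (less background
    mortality); otherwise LGD remains under 6-monthly surveillance with
    competing progression and reversion. Returns the matrix and an audit
    log of any row renormalisations.
    """
    if origin not in ORIGINS:
        raise ValueError(f"unknown origin {origin!r}")
    p = spec.params
    dt = spec.cycle_length
    c = lambda name: rate_to_probability(p[name], dt)  # noqa: E731

    p_bg = c("background_mortality_rate")
    fe = p[f"frac_eac_given_progression_{origin}"]
    fadv = p["frac_eac_advanced"]
    audit: list[str] = []
    P = np.zeros((N_STATES, N_STATES))

    # non-dysplastic tunnel: recurrence of LGD, slow direct progression,
    # otherwise the surveillance interval lengthens 6m -> 12m -> 24m
    fe_nd = p["frac_eac_given_progression_nd"]
    nd_prog = c("nd_progression_rate")
    nd_lgd = c("nd_lgd_recurrence_rate")
    for row, nxt in (
        ("NDBE_surv6m", "NDBE_surv12m"),
        ("NDBE_surv12m", "NDBE_surv24m"),
        ("NDBE_surv24m", "NDBE_surv24m"),
    ):
        flows = {
            "LGD": nd_lgd,
            "HGD": nd_prog * (1 - fe_nd),
            "EAC_T1a": nd_prog * fe_nd * (1 - fadv),
            "EAC_advanced": nd_prog * fe_nd * fadv,
            "other_death": p_bg,
        }
        # remainder moves down the tunnel (or stays at the 24m interval)
        i = IDX[row]
        total = sum(flows.values())
        for name, q in flows.items():
            P[i, IDX[name]] += q
        P[i, IDX[nxt]] += 1.0 - total

    if strategy.ablates(origin):
        _set_row(P, "LGD", {"post_RFA": 1.0 - p_bg, "other_death": p_bg}, "LGD", audit)
    else:
        prog = c(f"lgd_progression_rate_{origin}")
        _set_row(
            P,
            "LGD",
            {
                "HGD": prog * (1 - fe),
                "EAC_T1a": prog * fe * (1 - fadv),
                "EAC_advanced": prog * fe * fadv,
                "NDBE_surv12m": c("lgd_reversion_rate"),
                "other_death": p_bg,
            },
            "LGD",
            audit,
        )

    _set_row(
        P,
        "HGD",
        {
            "post_RFA": p["hgd_detection_prob_per_cycle"] * (1 - p_bg),
            "EAC_T1a": c("hgd_eac_rate") * (1 - fadv),
            "EAC_advanced": c("hgd_eac_rate") * fadv,
            "other_death": p_bg,
        },
        "HGD",
        audit,
    )
    _set_row(
        P,
        "EAC_T1a",
        {
            "post_EMR_RFA": p["t1a_detection_prob_per_cycle"] * (1 - p_bg),
            "EAC_advanced": c("t1a_progression_rate"),
            "cancer_death": c("t1a_mortality_rate"),
            "other_death": p_bg,
        },
        "EAC_T1a",
        audit,
    )
    _set_row(
        P,
        "EAC_advanced",
        {
            "cancer_death": c("eac_advanced_mortality_rate"),
            "other_death": p_bg,
        },
        "EAC_advanced",
        audit,
    )
    # residual risk after ablation: dysplasia recurrence plus a small direct
    # progression hazard (eradication is not fully protective)
    prfa = c("post_rfa_progression_rate")
    _set_row(
        P,
        "post_RFA",
        {
            "LGD": c("post_rfa_recurrence_rate"),
            "HGD": prfa * (1 - fe_nd),
            "EAC_T1a": prfa * fe_nd * (1 - fadv),
            "EAC_advanced": prfa * fe_nd * fadv,
            "other_death": p_bg,
        },
        "post_RFA",
        audit,
    )
    _set_row(
        P,
        "post_EMR_RFA",
        {
            "EAC_advanced": c("post_emr_recurrence_rate"),
            "cancer_death": c("t1a_mortality_rate"),
            "other_death": p_bg,
        },
        "post_EMR_RFA",
        audit,
    )
    P[IDX["cancer_death"], IDX["cancer_death"]] = 1.0
    P[IDX["other_death"], IDX["other_death"]] = 1.0
    return P, audit


def event_payoff_matrices(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-transition cost and disutility matrices (same for every strategy;
    strategies differ only in which transitions carry flow).

    RFA and EMR events carry procedure cost, a one-off utility decrement,
    and the expected cost/disutility of complications. Entry into advanced
    cancer triggers the stage-appropriate-care payoff bundle.
    """
    p = spec.params
    EC = np.zeros((N_STATES, N_STATES))
    ED = np.zeros((N_STATES, N_STATES))
    rfa_cost = p["cost_rfa"] + p["rfa_complication_prob"] * p["cost_rfa_complication"]
    rfa_dis = p["disutility_rfa"] + p["rfa_complication_prob"] * p["disutility_rfa_complication"]
    for src in STATE_NAMES:
        if src in ("cancer_death", "other_death"):
            continue
        # any ablation (from LGD or HGD) is an RFA event
        if src != "post_RFA":
            EC[IDX[src], IDX["post_RFA"]] += rfa_cost
            ED[IDX[src], IDX["post_RFA"]] += rfa_dis
        if src != "post_EMR_RFA":
            EC[IDX[src], IDX["post_EMR_RFA"]] += p["cost_emr"] + rfa_cost
            ED[IDX[src], IDX["post_EMR_RFA"]] += p["disutility_emr"] + rfa_dis
        if src != "EAC_advanced":
            EC[IDX[src], IDX["EAC_advanced"]] += p["cost_advanced_care_event"]
    return EC, ED


def state_payoffs(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle state costs and annual state utilities.

    Endoscopy costs are amortised over the surveillance interval: a state
    under 12-monthly surveillance accrues half an endoscopy per 6-month
    cycle, a 24-monthly state a quarter.
    """
    p = spec.params
    ce = p["cost_endoscopy"]
    costs = np.zeros(N_STATES)
    costs[IDX["NDBE_surv6m"]] = ce
    costs[IDX["NDBE_surv12m"]] = ce / 2
    costs[IDX["NDBE_surv24m"]] = ce / 4
    costs[IDX["LGD"]] = ce                      # 6-monthly while LGD present
    costs[IDX["HGD"]] = ce
    costs[IDX["EAC_T1a"]] = ce
    costs[IDX["EAC_advanced"]] = p["cost_advanced_care_cycle"]
    costs[IDX["post_RFA"]] = ce / 2             # 12-monthly post-ablation checks
    costs[IDX["post_EMR_RFA"]] = ce / 2

    utils = np.zeros(N_STATES)
    utils[IDX["NDBE_surv6m"]] = p["utility_ndbe"]
    utils[IDX["NDBE_surv12m"]] = p["utility_ndbe"]
    utils[IDX["NDBE_surv24m"]] = p["utility_ndbe"]
    utils[IDX["LGD"]] = p["utility_lgd"]
    utils[IDX["HGD"]] = p["utility_hgd"]
    utils[IDX["EAC_T1a"]] = p["utility_eac_t1a"]
    utils[IDX["EAC_advanced"]] = p["utility_eac_advanced"]
    utils[IDX["post_RFA"]] = p["utility_post_rfa"]
    utils[IDX["post_EMR_RFA"]] = p["utility_post_emr"]
    return costs, utils


# ---------------------------------------------------------------------------
# engine

def run_markov(P: np.ndarray, start: np.ndarray, n_cycles: int) -> CohortTrace:
    """Propagate a cohort distribution through ``n_cycles`` applications of P."""
    P = np.asarray(P, dtype=float)
    rowsums = P.sum(axis=1)
    bad = np.where(~np.isclose(rowsums, 1.0, atol=1e-9))[0]
    if bad.size:
        i = int(bad[0])
        name = STATE_NAMES[i] if P.shape[0] == N_STATES else str(i)
        raise ValueError(f"transition row {name} sums to {rowsums[i]!r}, not 1")
    if np.any(P < -1e-15):
        raise ValueError("transition matrix has negative entries")
    start = np.asarray(start, dtype=float)
    if abs(start.sum() - 1.0) > 1e-9:
        raise ValueError("start distribution must sum to 1")
    occ = np.empty((n_cycles + 1, P.shape[0]))
    occ[0] = start
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ P
    names = STATE_NAMES if P.shape[0] == N_STATES else tuple(
        f"s{i}" for i in range(P.shape[0])
    )
    return CohortTrace(occ, names)


def start_distribution() -> np.ndarray:
    """Each origin subcohort starts entirely in the LGD state."""
    start = np.zeros(N_STATES)
    start[IDX["LGD"]] = 1.0
    return start


def run_cohort(spec: ModelSpec, strategy: Strategy, origin: str | None = None) -> CohortTrace:
    """Cohort trace for one origin, or the origin-mix-weighted trace.

    The mixed trace is a presentation artifact (occupancy averaged over
    subcohorts); outcome accumulation always happens per origin so that
    transition flows stay consistent with their matrix.
    """
    spec.validate()
    if origin is not None:
        P, _ = apply_strategy_rewiring(spec, strategy, origin)
        return run_markov(P, start_distribution(), spec.n_cycles)
    occ = np.zeros((spec.n_cycles + 1, N_STATES))
    for o, w in spec.origin_mix.items():
        occ += w * run_cohort(spec, strategy, o).occupancy
    return CohortTrace(occ)


def accumulate_payoffs(
    trace: CohortTrace,
    P: np.ndarray,
    state_costs: np.ndarray,
    state_utilities_annual: np.ndarray,
    cycle_length: float,
    discount_rate_annual: float = 0.0,
    event_costs: np.ndarray | None = None,
    event_disutilities: np.ndarray | None = None,
    incidence_selector: np.ndarray | None = None,
) -> EconOutcome:
    """Payoff accumulation over any trace/matrix pair.

    Convention: state payoffs accrue on start-of-cycle occupancy (state
    costs are per cycle, utilities per year scaled by the cycle length);
    event payoffs on within-cycle transition flow; both discounted at the
    cycle's start index. No half-cycle correction is applied.
    ``incidence_selector`` is an optional 0/1 matrix marking transitions
    counted as incident events (undiscounted).
    """
    occ = trace.occupancy
    n_states = occ.shape[1]
    for name, m in (("event_costs", event_costs),
                    ("event_disutilities", event_disutilities),
                    ("incidence_selector", incidence_selector)):
        if m is not None and m.shape != (n_states, n_states):
            raise ValueError(f"{name} shape {m.shape} does not match {n_states} states")
    if len(state_costs) != n_states or len(state_utilities_annual) != n_states:
        raise ValueError("state payoff vectors do not match the state count")
    dc = duc = dq = duq = inc = 0.0
    for t in range(occ.shape[0] - 1):
        d = discount_factor(t, discount_rate_annual, cycle_length)
        flow = occ[t][:, None] * P
        cost_t = float(occ[t] @ state_costs)
        if event_costs is not None:
            cost_t += float((flow * event_costs).sum())
        qaly_t = cycle_length * float(occ[t] @ state_utilities_annual)
        if event_disutilities is not None:
            qaly_t -= float((flow * event_disutilities).sum())
        dc += d * cost_t
        duc += cost_t
        dq += d * qaly_t
        duq += qaly_t
        if incidence_selector is not None:
            inc += float((flow * incidence_selector).sum())
    return EconOutcome(
        discounted_cost=dc,
        discounted_qaly=dq,
        cumulative_eac_incidence=inc,
        undiscounted_cost=duc,
        undiscounted_qaly=duq,
    )


def eac_incidence_selector() -> np.ndarray:
    """0/1 matrix marking first entries into cancer states (recurrence out
    of post-resection states is not a new incident cancer)."""
    eac_cols = [IDX[s] for s in EAC_STATES]
    recur_rows = [IDX[s] for s in EAC_RECURRENCE_SOURCES]
    sel = np.zeros((N_STATES, N_STATES))
    sel[:, eac_cols] = 1.0
    sel[recur_rows, :] = 0.0
    return sel


def accumulate_outcomes(
    trace: CohortTrace, spec: ModelSpec, strategy: Strategy, origin: str
) -> EconOutcome:
    """Discounted economic outcomes for one origin subcohort.

    Cumulative EAC incidence counts flow into cancer states from
    non-cancer sources (first diagnosis only), undiscounted. See
    :func:`accumulate_payoffs` for the accrual conventions.
    """
    if trace.occupancy.shape[0] - 1 != spec.n_cycles:
        raise ValueError("trace length does not match spec horizon")
    P, _ = apply_strategy_rewiring(spec, strategy, origin)
    EC, ED = event_payoff_matrices(spec)
    state_costs, state_utils = state_payoffs(spec)
    return accumulate_payoffs(
        trace, P, state_costs, state_utils,
        cycle_length=spec.cycle_length,
        discount_rate_annual=spec.discount_rate_annual,
        event_costs=EC,
        event_disutilities=ED,
        incidence_selector=eac_incidence_selector(),
    )


def run_strategy(spec: ModelSpec, strategy: Strategy) -> EconOutcome:
    """End-to-end evaluation of one strategy: per-origin runs mixed by the
    base-case origin split."""
    spec.validate()
    totals = dict(discounted_cost=0.0, discounted_qaly=0.0,
                  cumulative_eac_incidence=0.0, undiscounted_cost=0.0,
                  undiscounted_qaly=0.0)
    for origin, w in spec.origin_mix.items():
        trace = run_cohort(spec, strategy, origin)
        out = accumulate_outcomes(trace, spec, strategy, origin)
        for k in totals:
            totals[k] += w * getattr(out, k)
    return EconOutcome(**totals)
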