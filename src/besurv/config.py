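"""Model configuration: default parameter set, YAML serialisation, validation.

Every tunable input lives in a flat ``params`` mapping on
:class:`~besurv.markov.ModelSpec`. Each parameter carries a provenance
tag:

``study-observed``
    taken directly from the surveillance cohort's printed counts;
``study-calibrated``
    fitted by :mod:`besurv.calibration` against the cohort's person-year
    progression rates and LGD-course proportions;
``placeholder``
    a documented stand-in of realistic magnitude for an input whose
    source values (costs, utilities, downstream cancer-pathway
    probabilities) have not been transcribed into this repository.
    :func:`load_spec` warns about every placeholder so a run can never
    silently depend on one.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import yaml

from .markov import ModelSpec, ORIGINS

#: (value, provenance) for every model parameter. Rates are per year,
#: ``*_prob*`` entries are per-cycle or per-event probabilities, costs are
#: AUD, utilities are annual weights, disutilities one-off QALY decrements.
DEFAULT_PARAMS: dict[str, tuple[float, str]] = {
    # natural history of LGD, fitted to the cohort (see besurv.calibration)
    "lgd_progression_rate_index": (0.015216, "study-calibrated"),
    "lgd_progression_rate_surv": (0.045517, "study-calibrated"),
    "lgd_reversion_rate": (0.418778, "study-calibrated"),
    "nd_lgd_recurrence_rate": (0.053483, "study-calibrated"),
    # directly observed in the cohort
    "nd_progression_rate": (0.006457, "study-observed"),
    "frac_eac_given_progression_nd": (10 / 25, "study-observed"),
    "frac_eac_given_progression_index": (1 / 7, "study-observed"),
    "frac_eac_given_progression_surv": (5 / 14, "study-observed"),
    # downstream cancer pathway and treatment effectiveness
    "frac_eac_advanced": (0.15, "placeholder"),
    "hgd_detection_prob_per_cycle": (0.85, "placeholder"),
    "hgd_eac_rate": (0.10, "placeholder"),
    "t1a_detection_prob_per_cycle": (0.75, "placeholder"),
    "t1a_progression_rate": (0.30, "placeholder"),
    "t1a_mortality_rate": (0.02, "placeholder"),
    "eac_advanced_mortality_rate": (0.35, "placeholder"),
    "post_rfa_recurrence_rate": (0.02, "placeholder"),
    "post_rfa_progression_rate": (0.003, "placeholder"),
    "post_emr_recurrence_rate": (0.03, "placeholder"),
    "background_mortality_rate": (0.0088, "placeholder"),
    "rfa_complication_prob": (0.05, "placeholder"),
    # costs (AUD)
    "cost_endoscopy": (1500.0, "placeholder"),
    "cost_rfa": (7000.0, "placeholder"),
    "cost_emr": (5000.0, "placeholder"),
    "cost_rfa_complication": (6000.0, "placeholder"),
    "cost_advanced_care_event": (80000.0, "placeholder"),
    "cost_advanced_care_cycle": (2000.0, "placeholder"),
    # annual utilities by state
    "utility_ndbe": (0.97, "placeholder"),
    "utility_lgd": (0.93, "placeholder"),
    "utility_hgd": (0.90, "placeholder"),
    "utility_eac_t1a": (0.85, "placeholder"),
    "utility_eac_advanced": (0.50, "placeholder"),
    "utility_post_rfa": (0.95, "placeholder"),
    "utility_post_emr": (0.90, "placeholder"),
    # one-off event disutilities (QALY decrements)
    "disutility_rfa": (0.05, "placeholder"),
    "disutility_emr": (0.05, "placeholder"),
    "disutility_rfa_complication": (0.10, "placeholder"),
}

DEFAULT_SPEC_PATH = Path(__file__).parent / "data" / "default_model.yaml"


def default_spec() -> ModelSpec:
    """The shipped model configuration (6-month cycles, 35-year horizon,
    5% annual discounting, AU$50,000/QALY willingness-to-pay, origin mix
    52% index-LGD / 48% surveillance-LGD)."""
    return ModelSpec(
        params={k: v for k, (v, _) in DEFAULT_PARAMS.items()},
        provenance={k: tag for k, (_, tag) in DEFAULT_PARAMS.items()},
    )


class SpecValidationError(ValueError):
    """Raised when a configuration file violates the model schema."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise SpecValidationError(msg)


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "cycle_length": spec.cycle_length,
        "horizon": spec.horizon,
        "discount_rate_annual": spec.discount_rate_annual,
        "wtp": spec.wtp,
        "origin_mix": dict(spec.origin_mix),
        "params": {k: float(v) for k, v in spec.params.items()},
        "provenance": dict(spec.provenance),
    }


def dump_spec(spec: ModelSpec, path: str | Path) -> None:
    """Write a spec as YAML (round-trips exactly through :func:`load_spec`)."""
    Path(path).write_text(
        yaml.safe_dump(spec_to_dict(spec), sort_keys=True, default_flow_style=False)
    )


def spec_from_dict(doc: dict) -> ModelSpec:
    _require(isinstance(doc, dict), "top level must be a mapping")
    known = {"cycle_length", "horizon", "discount_rate_annual", "wtp",
             "origin_mix", "params", "provenance"}
    unknown = set(doc) - known
    _require(not unknown, f"unknown top-level keys: {sorted(unknown)}")
    _require("params" in doc, "missing required key 'params'")
    params = doc["params"]
    _require(isinstance(params, dict), "'params' must be a mapping")
    missing = set(DEFAULT_PARAMS) - set(params)
    _require(not missing, f"params missing entries: {sorted(missing)}")
    extra = set(params) - set(DEFAULT_PARAMS)
    _require(not extra, f"params has unknown entries: {sorted(extra)}")
    for k, v in params.items():
        _require(isinstance(v, (int, float)), f"params.{k} must be numeric, got {v!r}")
    spec = ModelSpec(
        params={k: float(v) for k, v in params.items()},
        cycle_length=float(doc.get("cycle_length", 0.5)),
        horizon=float(doc.get("horizon", 35.0)),
        discount_rate_annual=float(doc.get("discount_rate_annual", 0.05)),
        wtp=float(doc.get("wtp", 50_000.0)),
        origin_mix={str(k): float(v) for k, v in doc.get(
            "origin_mix", {"index": 0.52, "surv": 0.48}).items()},
        provenance={str(k): str(v) for k, v in doc.get("provenance", {}).items()},
    )
    try:
        spec.validate()
    except ValueError as exc:
        raise SpecValidationError(str(exc)) from exc
    return spec


def load_spec(path: str | Path | None = None, warn_placeholders: bool = True) -> ModelSpec:
    """Load and validate a model configuration.

    With ``path=None`` the shipped default is returned. Parameters tagged
    ``placeholder`` trigger a single consolidated warning naming them.
    """
    if path is None:
        spec = default_spec()
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"model spec not found: {p}")
        doc = yaml.safe_load(p.read_text())
        spec = spec_from_dict(doc)
    if warn_placeholders:
        ph = sorted(k for k, tag in spec.provenance.items() if tag == "placeholder")
        if ph:
            warnings.warn(
                f"{len(ph)} parameter(s) are documented placeholders awaiting "
                f"source values: {', '.join(ph)}",
                stacklevel=2,
            )
    return spec
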