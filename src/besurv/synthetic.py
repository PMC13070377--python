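"""Synthetic surveillance-cohort generator.

Emulates a single-centre Barrett's esophagus surveillance cohort: three
groups (non-dysplastic throughout, LGD at the index endoscopy, LGD arising
during surveillance), exponential progression to HGD/EAC at group-specific
hazards, administrative censoring matched to the observed follow-up
distribution, and LGD-course labels (reverted / back-and-forth /
persistent).

The defaults encode the study conditions the statistics module is meant to
reproduce: group sizes 727/97/90, progression hazards 0.6457/1.0014/2.1807
per 100 person-years, per-group mean follow-up 5.3/7.2/7.1 years (pooled
~5.7 y), and LGD-course probabilities 0.690/0.198/0.112.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_stats import Group, GROUP_ORDER

#: Maximum follow-up in years (the surveillance program's observation window).
STUDY_WINDOW_YEARS = 21.0

LGD_COURSES = ("reverted", "back_and_forth", "persistent")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the generator; defaults are the study conditions."""

    group_sizes: tuple[int, int, int] = (727, 97, 90)
    #: per-year progression hazards (ND, LGD at entry, LGD during surveillance)
    progression_hazards: tuple[float, float, float] = (0.006457, 0.010014, 0.021807)
    #: per-group mean and SD of administrative follow-up, in years
    followup_mean: tuple[float, float, float] = (5.3, 7.2, 7.1)
    followup_sd: tuple[float, float, float] = (4.4, 5.8, 5.0)
    #: probabilities over (reverted, back_and_forth, persistent) LGD courses
    lgd_course_probs: tuple[float, float, float] = (0.690, 0.198, 0.112)
    #: P(EAC | progression) per group, from the observed event-type splits
    event_type_split: tuple[float, float, float] = (10 / 25, 1 / 7, 5 / 14)
    #: mean and SD of time under surveillance before LGD arises (group 3 only)
    time_to_lgd_mean: float = 3.6
    time_to_lgd_sd: float = 3.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.progression_hazards):
            raise ValueError("progression hazards must be non-negative")
        if any(n < 0 for n in self.group_sizes):
            raise ValueError("group sizes must be non-negative")
        if abs(sum(self.lgd_course_probs) - 1.0) > 1e-12:
            raise ValueError("lgd_course_probs must sum to 1")
        if any(p < 0 or p > 1 for p in self.event_type_split):
            raise ValueError("event_type_split entries must be probabilities")
        if any(m <= 0 for m in self.followup_mean) or any(s <= 0 for s in self.followup_sd):
            raise ValueError("follow-up moments must be positive")


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched gamma (shape, scale)."""
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


def _truncated_gamma(rng: np.random.Generator, mean: float, sd: float, size: int,
                     upper: float = STUDY_WINDOW_YEARS) -> np.ndarray:
    """Gamma draws truncated to (0, upper] by resampling; the truncation mass
    at the defaults is a few percent so resampling converges immediately."""
    shape, scale = _gamma_params(mean, sd)
    x = rng.gamma(shape, scale, size)
    bad = (x > upper) | (x <= 0)
    while bad.any():
        x[bad] = rng.gamma(shape, scale, int(bad.sum()))
        bad = (x > upper) | (x <= 0)
    return x


def generate_cohort(spec: SyntheticCohortSpec | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort.

    Per patient: an administrative censoring time ``C`` (truncated gamma
    matched to the group's follow-up moments) and an exponential
    progression time ``T`` at the group hazard; ``person_years =
    min(T, C)`` and ``event = [T <= C]``. Event types (HGD vs EAC) and,
    for LGD patients, course labels and (group 3) time-to-LGD are drawn
    independently. Fully reproducible from ``spec.seed``: each group uses
    a child stream spawned deterministically from the top-level seed.

    Returns a DataFrame with the analysis schema ``patient_id, group,
    person_years, event, event_type`` plus the extra columns
    ``lgd_course`` and ``time_to_lgd`` (NA where not applicable).
    """
    spec = spec or SyntheticCohortSpec()
    seq = np.random.SeedSequence(spec.seed)
    frames = []
    offset = 0
    for gi, group in enumerate(GROUP_ORDER):
        n = spec.group_sizes[gi]
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(gi,)))
        if n == 0:
            continue
        censor = _truncated_gamma(rng, spec.followup_mean[gi], spec.followup_sd[gi], n)
        hazard = spec.progression_hazards[gi]
        t_prog = np.full(n, np.inf) if hazard == 0 else rng.exponential(1.0 / hazard, n)
        event = t_prog <= censor
        person_years = np.minimum(t_prog, censor)
        is_eac = rng.random(n) < spec.event_type_split[gi]
        event_type = np.where(event, np.where(is_eac, "EAC", "HGD"), "NA")
        if group is Group.ND:
            course = np.full(n, "NA", dtype=object)
            time_to_lgd = np.full(n, np.nan)
        else:
            course = rng.choice(LGD_COURSES, size=n, p=spec.lgd_course_probs)
            if group is Group.LGD_SURV:
                time_to_lgd = _truncated_gamma(
                    rng, spec.time_to_lgd_mean, spec.time_to_lgd_sd, n
                )
            else:
                time_to_lgd = np.full(n, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"P{offset + i + 1:05d}" for i in range(n)],
                    "group": group.value,
                    "person_years": person_years,
                    "event": event.astype(int),
                    "event_type": event_type,
                    "lgd_course": course,
                    "time_to_lgd": time_to_lgd,
                }
            )
        )
        offset += n
    if not frames:
        return pd.DataFrame(
            columns=[
                "patient_id", "group", "person_years", "event",
                "event_type", "lgd_course", "time_to_lgd",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def fixture_table4():
    """The observed per-group event/exposure totals, as packaged counts.

    25 events over 3872 person-years (ND, n=727), 7 over 699 (LGD at entry,
    n=97), 14 over 642 (LGD during surveillance, n=90).
    """
    from .cohort_stats import GroupCounts

    return [
        GroupCounts(Group.ND, 727, 25, 3872.0),
        GroupCounts(Group.LGD_ENTRY, 97, 7, 699.0),
        GroupCounts(Group.LGD_SURV, 90, 14, 642.0),
    ]
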