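"""First-year decision tree and lifetime Markov cohort model.

Health states mirror the trial endpoints: event-free, non-fatal MI, non-fatal
stroke, death.  The first post-event year is a tunnel state (``MI_Y1`` /
``STROKE_Y1``) so that first-year hazard ratios and first-year event costs
apply exactly once; afterwards patients sit in the corresponding post-event
state until death.  After a non-fatal event no further events occur.

Timing conventions (documented in the methods note):

* cycle length 1 year; Markov cycle ``t`` spans ages ``start_age + t`` to
  ``start_age + t + 1`` with background mortality taken at age
  ``start_age + t``;
* a trace row ``t`` records the state distribution at the *start* of cycle
  ``t`` — row 1 is the decision-tree end distribution — and all rewards for
  cycle ``t`` accrue on that distribution;
* within a cycle, death acts first and the annual event probabilities split
  the survivors, which keeps row sums exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import (
    ArmYearOneInputs,
    CohortSpec,
    CostInputs,
    HazardRatioSet,
    LifeTable,
    LongTermInputs,
    ModelConfig,
)

__all__ = [
    "StateId",
    "StateDistribution",
    "YearOneResult",
    "MarkovTrace",
    "run_year_one",
    "apply_hazard_ratio",
    "annual_death_prob",
    "run_markov",
    "LIVING_STATES",
]

_SUM_TOL = 1e-12


class StateId(str, Enum):
    NO_EVENT = "no_event"
    MI_Y1 = "mi_y1"  # tunnel: first year after a non-fatal MI
    MI_POST = "mi_post"
    STROKE_Y1 = "stroke_y1"  # tunnel: first year after a non-fatal stroke
    STROKE_POST = "stroke_post"
    DEAD = "dead"


_ORDER = list(StateId)
LIVING_STATES = tuple(s for s in _ORDER if s is not StateId.DEAD)


@dataclass(frozen=True)
class StateDistribution:
    """Proportions of the cohort per state; non-negative, summing to 1."""

    occupancy: Mapping[StateId, float]

    def __post_init__(self) -> None:
        occ = {s: float(self.occupancy.get(s, 0.0)) for s in _ORDER}
        if any(v < -_SUM_TOL for v in occ.values()):
            raise ValueError("negative state occupancy")
        total = sum(occ.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state occupancy sums to {total!r}, not 1")
        object.__setattr__(self, "occupancy", occ)

    def __getitem__(self, state: StateId) -> float:
        return self.occupancy[state]

    @property
    def living(self) -> float:
        return 1.0 - self.occupancy[StateId.DEAD]

    def as_array(self) -> np.ndarray:
        return np.array([self.occupancy[s] for s in _ORDER])


@dataclass(frozen=True)
class YearOneResult:
    """Decision-tree outcome of one arm's first year (undiscounted)."""

    arm_label: str
    end_distribution: StateDistribution
    life_years: float
    qalys: float
    cost: float


@dataclass(frozen=True)
class MarkovTrace:
    """Start-of-cycle state distributions, cycle 1 onwards.

    ``final`` holds the distribution after the last modelled transition, so
    newly-dead proportions are defined for every cycle in the trace.
    """

    cycles: tuple[tuple[int, int, StateDistribution], ...]  # (t, age, distribution)
    final: StateDistribution

    def newly_dead(self) -> np.ndarray:
        """Proportion dying during each cycle of the trace."""
        dead = [dist[StateId.DEAD] for _, _, dist in self.cycles]
        dead.append(self.final[StateId.DEAD])
        return np.diff(np.array(dead))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cycle": t, "age": age, **{s.value: dist[s] for s in _ORDER}}
            for t, age, dist in self.cycles
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Inflate an annual probability by a hazard ratio: ``1 - (1-p)^hr``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return 1.0 - (1.0 - p) ** hr


_STATE_HR = {
    StateId.NO_EVENT: "hr_no_event",
    StateId.MI_Y1: "hr_mi_y1",
    StateId.MI_POST: "hr_mi_y2plus",
    StateId.STROKE_Y1: "hr_stroke_y1",
    StateId.STROKE_POST: "hr_stroke_y2plus",
}


def annual_death_prob(
    age: int,
    cohort: CohortSpec,
    life_table: LifeTable,
    longterm: LongTermInputs,
    hrs: HazardRatioSet,
    state: StateId,
    cycles_since_event: int = 0,
) -> float:
    """Annual probability of death for a living state at a given age.

    The sex-weighted life-table probability and the fatal-CV probability are
    combined on the hazard scale and the whole hazard is multiplied by the
    state's hazard ratio (first vs later post-event years are distinguished
    by the tunnel states; ``cycles_since_event`` is accepted for interface
    completeness).
    """
    if state is StateId.DEAD:
        return 0.0
    q_bg = life_table.sex_weighted_qx(age, cohort.male_fraction)
    if q_bg >= 1.0:
        return 1.0
    hazard = -np.log1p(-q_bg)
    if longterm.q_cv_fatal > 0:
        hazard += -np.log1p(-longterm.q_cv_fatal)
    hr = getattr(hrs, _STATE_HR[state])
    return float(-np.expm1(-hr * hazard))


def run_year_one(
    arm: ArmYearOneInputs, costs: CostInputs, drug_dtc: float
) -> YearOneResult:
    """Evaluate the first-year decision tree for one arm.

    Life-years credit decedents half a year; QALYs weight each branch by its
    observed utility (the death utility represents the average within-year
    accrual of decedents); costs comprise first-year event costs, the death
    cost for first-year decedents, and drug cost with decedents accruing
    ``drug_death_fraction`` of a treatment year.
    """
    dist = StateDistribution(
        {
            StateId.NO_EVENT: arm.p_no_event,
            StateId.MI_Y1: arm.p_mi,
            StateId.STROKE_Y1: arm.p_stroke,
            StateId.DEAD: arm.p_death,
        }
    )
    life_years = 1.0 - 0.5 * arm.p_death
    qalys = (
        arm.p_no_event * arm.u_no_event
        + arm.p_mi * arm.u_mi
        + arm.p_stroke * arm.u_stroke
        + arm.p_death * arm.u_death
    )
    drug_cost = costs.drug_days * drug_dtc * (
        1.0 - arm.p_death * (1.0 - costs.drug_death_fraction)
    )
    cost = (
        arm.p_mi * costs.c_mi_y1
        + arm.p_stroke * costs.c_stroke_y1
        + arm.p_death * costs.c_death
        + drug_cost
    )
    return YearOneResult(
        arm_label=arm.arm_label,
        end_distribution=dist,
        life_years=life_years,
        qalys=qalys,
        cost=cost,
    )


def run_markov(
    start: StateDistribution,
    config: ModelConfig,
    life_table: LifeTable,
    *,
    living_floor: float = 1e-9,
) -> MarkovTrace:
    """Propagate the cohort from the end of year 1 until extinction or horizon.

    From the event-free state the annual probabilities ``q_mi`` and
    ``q_stroke`` route survivors into the tunnel states; tunnel occupants
    move on to the post-event states; post-event states only exit through
    death.  Death competes by acting first, events split the survivors.
    """
    lt = config.longterm
    hrs = config.hazard_ratios
    cohort = config.cohort
    v = start.as_array()
    idx = {s: i for i, s in enumerate(_ORDER)}
    rows: list[tuple[int, int, StateDistribution]] = []
    t = 0
    while True:
        t += 1
        age = cohort.start_age + t
        living = v[: idx[StateId.DEAD]].sum() + 0.0
        if age > cohort.max_age or age > life_table.max_age or living < living_floor:
            t -= 1
            break
        rows.append((t, age, StateDistribution(dict(zip(_ORDER, v)))))
        death = {
            s: annual_death_prob(age, cohort, life_table, lt, hrs, s)
            for s in LIVING_STATES
        }
        new = np.zeros_like(v)
        ne_surv = v[idx[StateId.NO_EVENT]] * (1.0 - death[StateId.NO_EVENT])
        new[idx[StateId.MI_Y1]] = ne_surv * lt.q_mi
        new[idx[StateId.STROKE_Y1]] = ne_surv * lt.q_stroke
        new[idx[StateId.NO_EVENT]] = ne_surv * (1.0 - lt.q_mi - lt.q_stroke)
        new[idx[StateId.MI_POST]] = (
            v[idx[StateId.MI_Y1]] * (1.0 - death[StateId.MI_Y1])
            + v[idx[StateId.MI_POST]] * (1.0 - death[StateId.MI_POST])
        )
        new[idx[StateId.STROKE_POST]] = (
            v[idx[StateId.STROKE_Y1]] * (1.0 - death[StateId.STROKE_Y1])
            + v[idx[StateId.STROKE_POST]] * (1.0 - death[StateId.STROKE_POST])
        )
        new[idx[StateId.DEAD]] = 1.0 - new[: idx[StateId.DEAD]].sum()
        v = new
    return MarkovTrace(cycles=tuple(rows), final=StateDistribution(dict(zip(_ORDER, v))))
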