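"""Discounted costs, life-years, QALYs and incremental comparison.

Year 1 (the decision tree) is undiscounted; Markov cycle ``t`` is discounted
by ``(1 + r)^-t``.  Each cycle's rewards accrue on the start-of-cycle
occupancy recorded in the trace.  The death cost is charged to first-year
decedents in the decision tree; charging it for later deaths as well is a
configurable option (off by default, see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np

from .markov import MarkovTrace, StateId, YearOneResult, run_markov, run_year_one
from .parameters import DiscountSpec, LifeTable, LongTermInputs, ModelConfig

__all__ = [
    "ArmResult",
    "Dominance",
    "CEAResult",
    "StateValueSchedule",
    "discount_factor",
    "state_utility",
    "accumulate",
    "compare",
    "run_arm",
    "run_cea",
]

ARMS = ("ticagrelor", "clopidogrel")


def discount_factor(year_index: int, rate: float) -> float:
    """``(1 + rate)^-year_index``; the first model year carries index 0."""
    if year_index < 0:
        raise ValueError("year index must be >= 0")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-year_index)


def state_utility(state: StateId, age: int, longterm: LongTermInputs) -> float:
    """Age-band utility minus the event decrement; zero when dead."""
    if state is StateId.DEAD:
        return 0.0
    u = longterm.band_utility(age)
    if state is StateId.MI_Y1:
        u -= longterm.du_mi_y1
    elif state is StateId.MI_POST:
        u -= longterm.du_mi_y2plus
    elif state is StateId.STROKE_Y1:
        u -= longterm.du_stroke_y1
    elif state is StateId.STROKE_POST:
        u -= longterm.du_stroke_y2plus
    return max(u, 0.0)


@dataclass(frozen=True)
class StateValueSchedule:
    """Annual cost per state and age-dependent utility for the Markov phase."""

    longterm: LongTermInputs
    state_costs: Mapping[StateId, float]
    death_cost: float
    charge_death_cost: bool

    @classmethod
    def from_config(cls, config: ModelConfig) -> "StateValueSchedule":
        c = config.costs
        opts = config.analysis
        costs = {
            StateId.NO_EVENT: c.c_no_event_annual if opts.include_no_event_cost else 0.0,
            StateId.MI_Y1: c.c_mi_y1
            + (c.indirect_mi_y1 if opts.include_indirect_costs else 0.0),
            StateId.MI_POST: c.c_mi_y2plus,
            StateId.STROKE_Y1: c.c_stroke_y1
            + (c.indirect_stroke_y1 if opts.include_indirect_costs else 0.0),
            StateId.STROKE_POST: c.c_stroke_y2plus
            + (c.indirect_stroke_y2plus if opts.include_indirect_costs else 0.0),
            StateId.DEAD: 0.0,
        }
        return cls(
            longterm=config.longterm,
            state_costs=costs,
            death_cost=c.c_death,
            charge_death_cost=opts.charge_death_cost_in_markov,
        )

    def cost_of(self, state: StateId) -> float:
        return self.state_costs[state]

    def utility_of(self, state: StateId, age: int) -> float:
        return state_utility(state, age, self.longterm)


@dataclass(frozen=True)
class ArmResult:
    """Discounted lifetime totals for one strategy (per average patient)."""

    arm_label: str
    cost: float
    life_years: float
    qalys: float

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ValueError("QALYs cannot exceed life-years")


class Dominance(str, Enum):
    NONE = "none"
    TICAGRELOR_DOMINANT = "ticagrelor_dominant"
    CLOPIDOGREL_DOMINANT = "clopidogrel_dominant"


@dataclass(frozen=True)
class CEAResult:
    ticagrelor: ArmResult
    clopidogrel: ArmResult
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_ly: float | None
    icer_qaly: float | None
    dominance: Dominance

    def as_dict(self) -> dict:
        return {
            "ticagrelor": vars(self.ticagrelor).copy(),
            "clopidogrel": vars(self.clopidogrel).copy(),
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_ly": self.icer_ly,
            "icer_qaly": self.icer_qaly,
            "dominance": self.dominance.value,
        }


def accumulate(
    year_one: YearOneResult,
    trace: MarkovTrace,
    schedule: StateValueSchedule,
    discount: DiscountSpec,
) -> ArmResult:
    """Fold the decision-tree year and the Markov trace into lifetime totals."""
    cost = year_one.cost
    ly = year_one.life_years
    qaly = year_one.qalys
    newly_dead = trace.newly_dead() if schedule.charge_death_cost else None
    for i, (t, age, dist) in enumerate(trace.cycles):
        df_c = discount_factor(t, discount.rate_costs)
        df_e = discount_factor(t, discount.rate_effects)
        ly += df_e * dist.living
        qaly += df_e * sum(
            dist[s] * schedule.utility_of(s, age) for s in StateId if s is not StateId.DEAD
        )
        cycle_cost = sum(dist[s] * schedule.cost_of(s) for s in StateId)
        if newly_dead is not None:
            cycle_cost += newly_dead[i] * schedule.death_cost
        cost += df_c * cycle_cost
    return ArmResult(
        arm_label=year_one.arm_label, cost=cost, life_years=ly, qalys=qaly
    )


def compare(t: ArmResult, c: ArmResult) -> CEAResult:
    """Incremental comparison (ticagrelor minus clopidogrel) with dominance.

    ICERs are reported only when the corresponding effect difference is
    non-zero and neither strategy dominates.
    """
    d_cost = t.cost - c.cost
    d_ly = t.life_years - c.life_years
    d_qaly = t.qalys - c.qalys
    if d_cost <= 0 and d_qaly >= 0 and (d_cost < 0 or d_qaly > 0):
        dom = Dominance.TICAGRELOR_DOMINANT
    elif d_cost >= 0 and d_qaly <= 0 and (d_cost > 0 or d_qaly < 0):
        dom = Dominance.CLOPIDOGREL_DOMINANT
    else:
        dom = Dominance.NONE
    icer_ly = d_cost / d_ly if (dom is Dominance.NONE and d_ly != 0) else None
    icer_qaly = d_cost / d_qaly if (dom is Dominance.NONE and d_qaly != 0) else None
    return CEAResult(
        ticagrelor=t,
        clopidogrel=c,
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_ly=icer_ly,
        icer_qaly=icer_qaly,
        dominance=dom,
    )


def run_arm(
    config: ModelConfig, arm_name: str, life_table: LifeTable
) -> tuple[ArmResult, MarkovTrace]:
    """Full pipeline for one arm: decision tree, Markov trace, accumulation."""
    arm = config.arm(arm_name)
    year_one = run_year_one(arm, config.costs, config.dtc(arm_name))
    trace = run_markov(year_one.end_distribution, config, life_table)
    schedule = StateValueSchedule.from_config(config)
    result = accumulate(year_one, trace, schedule, config.discount)
    return result, trace


def run_cea(config: ModelConfig, life_table: LifeTable) -> CEAResult:
    """Deterministic cost-effectiveness comparison of both strategies."""
    t_res, _ = run_arm(config, "ticagrelor", life_table)
    c_res, _ = run_arm(config, "clopidogrel", life_table)
    return compare(t_res, c_res)
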