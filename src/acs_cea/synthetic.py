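"""Synthetic inputs: trial-like patient-level data and life tables.

The original patient-level event times are not public, so every stage that
would consume them (Weibull fitting, probabilistic draws) is fed by a
generator that emulates a 12-month antiplatelet trial: per-endpoint Weibull
latent times, competing-risk resolution by earliest event, and
administrative censoring at the 6-, 9- or 12-month visit — mimicking an
event-driven trial in which part of the cohort leaves at interim visits.

Life tables come either from a Gompertz–Makeham hazard (fully synthetic) or
from the bundled reconstruction of the German 2009 period table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

from .parameters import ArmYearOneInputs, LifeTable, LongTermInputs, load_life_table
from .survival import WeibullFit, calibrate_from_probs

__all__ = [
    "IPDRecord",
    "GompertzMakehamParams",
    "ENDPOINTS",
    "CENSOR_TIMES",
    "generate_ipd",
    "generate_life_table",
    "bundled_life_table",
    "write_ipd_csv",
    "read_ipd_csv",
]

ENDPOINTS = ("mi", "stroke", "death")
CENSOR_TIMES = (0.5, 0.75, 1.0)
_DAY = 1.0 / 365.0

_BUNDLED_TABLES = ("synthetic_default", "german_2009")


@dataclass(frozen=True)
class IPDRecord:
    """One patient: follow-up time in years and what ended it."""

    patient_id: str
    arm: str
    time: float
    event: str  # "mi" | "stroke" | "death" | "censored"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.event not in ENDPOINTS + ("censored",):
            raise ValueError(f"unknown event kind {self.event!r}")


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard a + b*exp(c*age): background plus senescent component."""

    a: float = 5e-5
    b: float = 3.5e-5
    c: float = 0.095

    def __post_init__(self) -> None:
        if self.a < 0 or self.b <= 0 or self.c <= 0:
            raise ValueError("require a >= 0, b > 0, c > 0")

    def integrated_hazard(self, age: float) -> float:
        """Integral of the hazard over [age, age + 1]."""
        return self.a + (self.b / self.c) * (
            math.exp(self.c * (age + 1)) - math.exp(self.c * age)
        )


def generate_life_table(
    params: GompertzMakehamParams, age_range: tuple[int, int] = (0, 110)
) -> LifeTable:
    """Life table with ``qx = 1 - exp(-integrated hazard)``, forced to 1 terminally.

    Both sexes receive the same schedule; the generator models a single
    hazard, sex structure enters the cohort model through its male fraction.
    """
    lo, hi = age_range
    if hi < lo:
        raise ValueError("empty age range")
    ages = np.arange(lo, hi + 1)
    qx = np.array([1.0 - math.exp(-params.integrated_hazard(a)) for a in ages])
    qx[-1] = 1.0
    rows = [
        {"age": int(a), "sex": sex, "qx": float(q)}
        for sex in ("male", "female")
        for a, q in zip(ages, qx)
    ]
    return LifeTable(pd.DataFrame(rows))


def bundled_life_table(name: str) -> LifeTable:
    """Shipped life-table fixtures.

    ``synthetic_default`` is generated from the default Gompertz–Makeham
    parameters; ``german_2009`` is a synthetic reconstruction of the German
    2009 period table calibrated to published life expectancies (see the
    header of ``data/german_2009_synthetic.csv``).
    """
    if name == "synthetic_default":
        return generate_life_table(GompertzMakehamParams())
    if name == "german_2009":
        import importlib.resources

        resource = importlib.resources.files("acs_cea") / "data" / "german_2009_synthetic.csv"
        with importlib.resources.as_file(resource) as path:
            return load_life_table(path)
    raise KeyError(
        f"unknown life table {name!r}; bundled fixtures: {', '.join(_BUNDLED_TABLES)}"
    )


def _marginal_incidence(fits: Mapping[str, WeibullFit], endpoint: str) -> float:
    """12-month incidence of ``endpoint`` when latent times compete.

    Integrates f_e(t) * prod_{j != e} S_j(t) over (0, 1].
    """
    ke, le = fits[endpoint].shape, fits[endpoint].scale

    def integrand(t: float) -> float:
        log_fe = (
            math.log(ke) - math.log(le) + (ke - 1.0) * (math.log(t) - math.log(le))
            - (t / le) ** ke
        )
        log_s_others = -sum(
            (t / fits[j].scale) ** fits[j].shape for j in fits if j != endpoint
        )
        return math.exp(log_fe + log_s_others)

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return val


def _calibrated_latent_fits(
    arm: ArmYearOneInputs,
    year2_conditional: Mapping[str, float],
    rounds: int = 5,
    tol: float = 1e-3,
) -> dict[str, WeibullFit]:
    """Latent per-endpoint Weibulls whose competing marginals hit the targets.

    Shapes come from :func:`calibrate_from_probs`; scales are then adjusted by
    a fixed-point iteration (at most ``rounds``) so that the marginal
    12-month incidences under competing risks match the configured
    first-year probabilities to within ``tol`` (0.1% absolute).
    """
    targets = {"mi": arm.p_mi, "stroke": arm.p_stroke, "death": arm.p_death}
    active = {e: p for e, p in targets.items() if p > 0.0}
    fits: dict[str, WeibullFit] = {}
    adjusted = dict(active)
    for _ in range(rounds):
        fits = {
            e: calibrate_from_probs(
                min(adjusted[e], 0.999),
                year2_conditional.get(e) or min(adjusted[e], 0.999),
            )
            for e in active
        }
        realized = {e: _marginal_incidence(fits, e) for e in active}
        if all(abs(realized[e] - active[e]) <= tol for e in active):
            break
        for e in active:
            # scale the cumulative hazard at t=1 by the target/realized ratio
            h1 = -math.log1p(-min(adjusted[e], 0.999))
            h1 *= active[e] / max(realized[e], 1e-12)
            adjusted[e] = -math.expm1(-h1)
    return fits


def generate_ipd(
    arm_inputs: ArmYearOneInputs,
    n: int,
    censor_mix: Sequence[float] = (0.2, 0.2, 0.6),
    seed: int = 0,
    longterm: LongTermInputs | None = None,
) -> list[IPDRecord]:
    """Simulate ``n`` patients of one arm over 12 months.

    Latent event times are Weibull per endpoint, calibrated so the expected
    12-month cumulative incidence of each endpoint equals the arm's
    configured first-year probability (including the competing-risk
    correction).  Weibull shapes reflect the year-2 conditional
    probabilities in ``longterm`` when given, otherwise the exponential
    special case.  Each patient is administratively censored at the 6-, 9-
    or 12-month visit with probabilities ``censor_mix``.  Event times are
    recorded on a 1/365-year grid; output is deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(censor_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise ValueError("censor_mix must be three non-negative proportions summing to 1")

    if longterm is not None:
        year2 = {
            "mi": longterm.q_mi,
            "stroke": longterm.q_stroke,
            "death": longterm.q_cv_fatal,
        }
    else:
        year2 = {"mi": arm_inputs.p_mi, "stroke": arm_inputs.p_stroke, "death": arm_inputs.p_death}
    fits = _calibrated_latent_fits(arm_inputs, year2)

    rng = np.random.default_rng(seed)
    visit = rng.choice(np.asarray(CENSOR_TIMES), size=n, p=mix)
    latent = np.full((n, len(ENDPOINTS)), np.inf)
    for j, e in enumerate(ENDPOINTS):
        if e in fits:
            u = rng.random(n)
            latent[:, j] = fits[e].scale * (-np.log(u)) ** (1.0 / fits[e].shape)
    first = latent.argmin(axis=1)
    t_event = latent[np.arange(n), first]
    # day grid, at least one day, never beyond the visit that would censor
    t_rec = np.minimum(np.ceil(t_event / _DAY) * _DAY, visit)
    is_event = t_event <= visit

    records: list[IPDRecord] = []
    width = len(str(n))
    for i in range(n):
        if is_event[i]:
            records.append(
                IPDRecord(
                    patient_id=f"{arm_inputs.arm_label}-{i:0{width}d}",
                    arm=arm_inputs.arm_label,
                    time=max(float(t_rec[i]), _DAY),
                    event=ENDPOINTS[first[i]],
                )
            )
        else:
            records.append(
                IPDRecord(
                    patient_id=f"{arm_inputs.arm_label}-{i:0{width}d}",
                    arm=arm_inputs.arm_label,
                    time=float(visit[i]),
                    event="censored",
                )
            )
    return records


def write_ipd_csv(records: Iterable[IPDRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.patient_id, r.arm, r.time, r.event) for r in records],
        columns=["patient_id", "arm", "time", "event"],
    )
    frame.to_csv(path, index=False)


def read_ipd_csv(path: str | Path) -> list[IPDRecord]:
    frame = pd.read_csv(path)
    return [
        IPDRecord(str(r.patient_id), str(r.arm), float(r.time), str(r.event))
        for r in frame.itertuples(index=False)
    ]
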