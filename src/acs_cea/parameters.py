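"""Parameter set for the two-part decision model.

Everything a single cost-effectiveness run needs is collected in a
:class:`ModelConfig`: the cohort definition, per-arm first-year event
probabilities and utilities from the trial, long-term annual transition
probabilities, hazard ratios inflating background mortality after an event,
unit costs (2009 EUR), and discount rates.  Three default configurations are
bundled (overall ACS, NSTEMI/UA, STEMI; all restricted to the low-dose-ASA
population) together with life-table fixtures.

Configurations are YAML documents validated by pydantic; validation errors
name the offending field.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "CohortSpec",
    "ArmYearOneInputs",
    "LongTermInputs",
    "HazardRatioSet",
    "CostInputs",
    "DiscountSpec",
    "AnalysisOptions",
    "PSASpec",
    "ModelConfig",
    "LifeTable",
    "load_config",
    "load_life_table",
    "default_configs",
    "serialize_config",
    "COHORT_LABELS",
]

COHORT_LABELS = ("overall", "nstemi_ua", "stemi")

_DATA = importlib.resources.files("acs_cea") / "data"


class _Strict(BaseModel):
    model_config = {"extra": "forbid"}


class CohortSpec(_Strict):
    """Modelled patient cohort: starting age, sex mix and horizon."""

    label: str
    start_age: int = Field(gt=0)
    male_fraction: float = Field(ge=0.0, le=1.0)
    max_age: int = Field(le=110)
    cohort_scale: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _age_order(self) -> "CohortSpec":
        if not self.start_age < self.max_age:
            raise ValueError("start_age must be below max_age")
        return self


class ArmYearOneInputs(_Strict):
    """First-year (decision-tree) event probabilities and utilities for one arm."""

    arm_label: str
    p_mi: float = Field(ge=0.0, le=1.0, description="non-fatal MI, year 1")
    p_stroke: float = Field(ge=0.0, le=1.0, description="non-fatal stroke, year 1")
    p_death: float = Field(ge=0.0, le=1.0, description="all-cause death, year 1")
    u_no_event: float = Field(ge=0.0, le=1.0)
    u_mi: float = Field(ge=0.0, le=1.0)
    u_stroke: float = Field(ge=0.0, le=1.0)
    u_death: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _prob_sum(self) -> "ArmYearOneInputs":
        total = self.p_mi + self.p_stroke + self.p_death
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"p_mi + p_stroke + p_death = {total:.4f} exceeds 1 for arm "
                f"{self.arm_label!r}"
            )
        return self

    @property
    def p_no_event(self) -> float:
        return 1.0 - self.p_mi - self.p_stroke - self.p_death


class LongTermInputs(_Strict):
    """Annual transition probabilities and utilities beyond year 1.

    Probabilities apply from the no-event state and are held constant beyond
    year 2, matching the Weibull extrapolation they were derived from.
    Utilities are age-banded; events carry additive decrements.
    """

    q_mi: float = Field(ge=0.0, le=1.0)
    q_stroke: float = Field(ge=0.0, le=1.0)
    q_cv_fatal: float = Field(ge=0.0, le=1.0)
    u_no_event_by_age_band: dict[str, float]
    du_stroke_y1: float = Field(ge=0.0)
    du_stroke_y2plus: float = Field(ge=0.0)
    du_mi_y1: float = Field(ge=0.0)
    du_mi_y2plus: float = Field(ge=0.0)

    @field_validator("u_no_event_by_age_band")
    @classmethod
    def _bands(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != {"60-69", "70-79", "80+"}:
            raise ValueError("u_no_event_by_age_band must have bands 60-69, 70-79, 80+")
        for band, u in v.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility for band {band} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _checks(self) -> "LongTermInputs":
        if self.q_mi + self.q_stroke + self.q_cv_fatal > 1.0 + 1e-12:
            raise ValueError("q_mi + q_stroke + q_cv_fatal exceeds 1")
        u_min = min(self.u_no_event_by_age_band.values())
        for name in ("du_stroke_y1", "du_stroke_y2plus", "du_mi_y1", "du_mi_y2plus"):
            if getattr(self, name) > u_min + 1e-12:
                raise ValueError(f"{name} exceeds the smallest band utility")
        return self

    def band_utility(self, age: float) -> float:
        """No-event utility for the cohort's current integer age.

        Ages below 60 use the 60-69 band (no younger band is defined).
        """
        if age < 70:
            return self.u_no_event_by_age_band["60-69"]
        if age < 80:
            return self.u_no_event_by_age_band["70-79"]
        return self.u_no_event_by_age_band["80+"]


class HazardRatioSet(_Strict):
    """Hazard ratios applied to the combined background death hazard per state."""

    hr_no_event: float = Field(gt=0.0)
    hr_mi_y1: float = Field(gt=0.0)
    hr_mi_y2plus: float = Field(gt=0.0)
    hr_stroke_y1: float = Field(gt=0.0)
    hr_stroke_y2plus: float = Field(gt=0.0)


# HR sets quoted in the analysis: base case and the multinational ("Global")
# model alternative used in sensitivity analysis.
BASE_CASE_HRS = HazardRatioSet(
    hr_no_event=1.0, hr_mi_y1=1.6, hr_mi_y2plus=1.4, hr_stroke_y1=3.23, hr_stroke_y2plus=1.5
)
GLOBAL_MODEL_HRS = HazardRatioSet(
    hr_no_event=2.0, hr_mi_y1=6.0, hr_mi_y2plus=3.0, hr_stroke_y1=7.43, hr_stroke_y2plus=3.0
)


class CostInputs(_Strict):
    """Unit costs in 2009 EUR (statutory-health-insurance perspective)."""

    c_mi_y1: float = Field(ge=0.0)
    c_stroke_y1: float = Field(ge=0.0)
    c_mi_y2plus: float = Field(ge=0.0)
    c_stroke_y2plus: float = Field(ge=0.0)
    c_death: float = Field(ge=0.0)
    c_no_event_annual: float = Field(default=0.0, ge=0.0)
    indirect_mi_y1: float = Field(default=0.0, ge=0.0)
    indirect_stroke_y1: float = Field(default=0.0, ge=0.0)
    indirect_stroke_y2plus: float = Field(default=0.0, ge=0.0)
    dtc_ticagrelor: float = Field(ge=0.0, description="EUR per day")
    dtc_clopidogrel: float = Field(ge=0.0, description="EUR per day")
    drug_days: float = Field(default=365.0, ge=0.0)
    drug_death_fraction: float = Field(default=0.5, ge=0.0, le=1.0)


class DiscountSpec(_Strict):
    rate_costs: float = Field(ge=0.0)
    rate_effects: float = Field(ge=0.0)


class AnalysisOptions(_Strict):
    """Scenario toggles that change what the value schedule charges."""

    include_indirect_costs: bool = False
    include_no_event_cost: bool = False
    charge_death_cost_in_markov: bool = False


class PSASpec(_Strict):
    """Configuration of the probabilistic sensitivity analysis.

    The trial publication quantifies no standard errors, so the defaults are
    synthetic: utility SE 0.02; per-HR log-scale SD such that the 95% interval
    spans [HR/1.5, 1.5*HR]; first-year probabilities either from multivariate
    normal draws of fitted log-Weibull coefficients (``covariance_mvn``) or
    from beta draws around the base probabilities (``probability_beta``).
    """

    n_iterations: int = Field(default=10_000, ge=1)
    hr_lognormal_sd: dict[str, float] = Field(
        default_factory=lambda: {
            "hr_no_event": 0.0,  # base-case HR is exactly 1 (reference)
            "hr_mi_y1": 0.2069,
            "hr_mi_y2plus": 0.2069,
            "hr_stroke_y1": 0.2069,
            "hr_stroke_y2plus": 0.2069,
        }
    )
    utility_se: float = Field(default=0.02, ge=0.0)
    weibull_draw: Literal["covariance_mvn", "probability_beta"] = "covariance_mvn"
    beta_ess: float = Field(default=6500.0, gt=0.0)
    ipd_n_per_arm: int = Field(default=20_000, ge=100)
    redraw_cap: int = Field(default=100, ge=1)
    thresholds: list[float] = Field(
        default_factory=lambda: [float(x) for x in range(0, 51_000, 1_000)]
    )

    @field_validator("hr_lognormal_sd")
    @classmethod
    def _sds(cls, v: dict[str, float]) -> dict[str, float]:
        for key, sd in v.items():
            if key not in HazardRatioSet.model_fields:
                raise ValueError(f"unknown hazard-ratio field {key!r}")
            if sd < 0:
                raise ValueError(f"hr_lognormal_sd[{key!r}] must be >= 0")
        return v


class ModelConfig(_Strict):
    """Complete, validated parameter set for one cost-effectiveness analysis."""

    cohort: CohortSpec
    arm_ticagrelor: ArmYearOneInputs
    arm_clopidogrel: ArmYearOneInputs
    longterm: LongTermInputs
    hazard_ratios: HazardRatioSet
    costs: CostInputs
    discount: DiscountSpec
    life_table_ref: str
    analysis: AnalysisOptions = Field(default_factory=AnalysisOptions)
    psa: PSASpec = Field(default_factory=PSASpec)
    seed: int = 0

    def arm(self, name: str) -> ArmYearOneInputs:
        if name == "ticagrelor":
            return self.arm_ticagrelor
        if name == "clopidogrel":
            return self.arm_clopidogrel
        raise KeyError(f"unknown arm {name!r}")

    def dtc(self, name: str) -> float:
        if name == "ticagrelor":
            return self.costs.dtc_ticagrelor
        if name == "clopidogrel":
            return self.costs.dtc_clopidogrel
        raise KeyError(f"unknown arm {name!r}")


class LifeTable:
    """Annual death probabilities qx by integer age and sex.

    Thin wrapper around a DataFrame with columns ``age``, ``sex``
    (``male``/``female``) and ``qx``; ages must be contiguous per sex and the
    terminal qx must equal 1.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"age", "sex", "qx"}
        if not required.issubset(frame.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        frame = frame[["age", "sex", "qx"]].copy()
        frame["age"] = frame["age"].astype(int)
        self._qx: dict[str, np.ndarray] = {}
        ages_ref: np.ndarray | None = None
        for sex, grp in frame.groupby("sex"):
            if sex not in ("male", "female"):
                raise ValueError(f"unknown sex {sex!r} in life table")
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy()
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise ValueError(f"ages not contiguous for sex {sex!r}")
            if ages_ref is not None and not np.array_equal(ages, ages_ref):
                raise ValueError("age span differs between sexes")
            ages_ref = ages
            qx = grp["qx"].to_numpy(float)
            if np.any(qx < 0) or np.any(qx > 1):
                raise ValueError("qx outside [0, 1]")
            if qx[-1] != 1.0:
                raise ValueError("qx must equal 1 at the terminal age")
            self._qx[sex] = qx
        if set(self._qx) != {"male", "female"}:
            raise ValueError("life table must cover both sexes")
        assert ages_ref is not None
        self.min_age = int(ages_ref[0])
        self.max_age = int(ages_ref[-1])
        self.frame = frame.sort_values(["sex", "age"]).reset_index(drop=True)

    def qx(self, age: int, sex: str) -> float:
        if not self.min_age <= age <= self.max_age:
            raise ValueError(
                f"age {age} outside life-table span [{self.min_age}, {self.max_age}]"
            )
        return float(self._qx[sex][age - self.min_age])

    def sex_weighted_qx(self, age: int, male_fraction: float) -> float:
        """Cohort death probability combining sexes on the hazard scale."""
        qm = self.qx(age, "male")
        qf = self.qx(age, "female")
        if qm >= 1.0 or qf >= 1.0:
            return 1.0
        h = -male_fraction * np.log1p(-qm) - (1.0 - male_fraction) * np.log1p(-qf)
        return float(-np.expm1(-h))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def load_life_table(source: str | Path) -> LifeTable:
    """Read a life table from delimited text with header ``age,sex,qx``."""
    frame = pd.read_csv(source, sep=None, engine="python", comment="#")
    return LifeTable(frame)


def _build_config(doc: Mapping) -> ModelConfig:
    try:
        return ModelConfig.model_validate(doc)
    except Exception as exc:  # pydantic ValidationError carries field locations
        raise ValueError(f"invalid model configuration: {exc}") from exc


def load_config(source: str | Path | Mapping) -> ModelConfig:
    """Load and fully validate a model configuration.

    ``source`` may be a YAML/JSON file path or an already-parsed mapping.
    """
    if isinstance(source, Mapping):
        return _build_config(source)
    with open(source, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValueError(f"configuration document {source} is not a mapping")
    return _build_config(doc)


def serialize_config(config: ModelConfig) -> str:
    """YAML round-trip companion of :func:`load_config`."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)


def default_configs() -> dict[str, ModelConfig]:
    """The three bundled cohorts: overall ACS, NSTEMI/UA and STEMI.

    Returns freshly validated configurations so callers may mutate copies
    freely.
    """
    out: dict[str, ModelConfig] = {}
    for label in COHORT_LABELS:
        resource = _DATA / f"{label}.yaml"
        doc = yaml.safe_load(resource.read_text(encoding="utf-8"))
        out[label] = _build_config(doc)
    return out
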