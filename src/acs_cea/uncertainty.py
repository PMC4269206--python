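"""Probabilistic and deterministic sensitivity analysis.

The probabilistic sensitivity analysis re-draws the clinical-effect and
quality-of-life parameters and pushes every draw through the full model
(decision tree, Markov cohort, discounting):

* hazard ratios — log-normal around the base value (medians preserved);
* first-year event probabilities — either multivariate-normal draws of the
  log-Weibull coefficients fitted to synthetic patient-level data
  (``covariance_mvn``; the baseline normal deviate is shared between arms so
  that effect size and baseline risk stay correlated) or beta draws around
  the base probabilities (``probability_beta``);
* utilities and decrements — beta distributions matched to mean and
  standard error;
* costs — fixed, treated as known with certainty.

Deterministic scenario analysis re-runs the model under parameter
overrides (drug prices, alternative hazard-ratio sets, discount rates,
indirect-cost and no-event-cost toggles) and summarises one-way results as
a tornado ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .economics import CEAResult, Dominance, run_cea
from .markov import StateId  # noqa: F401  (re-exported for scenario tooling)
from .parameters import (
    GLOBAL_MODEL_HRS,
    LifeTable,
    ModelConfig,
    PSASpec,
    load_config,
)
from .survival import WeibullFit, calibrate_from_probs, conditional_annual_prob, fit_weibull_mle
from .synthetic import ENDPOINTS, generate_ipd

__all__ = [
    "PSADraw",
    "PSAResult",
    "CEACCurve",
    "ScenarioSpec",
    "draw_parameters",
    "run_psa",
    "ceac",
    "run_scenarios",
    "tornado",
    "bundled_scenario_set",
    "apply_overrides",
]


@dataclass(frozen=True)
class PSADraw:
    index: int
    delta_cost: float
    delta_ly: float
    delta_qaly: float


@dataclass(frozen=True)
class CEACCurve:
    """Probability that ticagrelor is cost-effective per willingness-to-pay."""

    points: tuple[tuple[float, float], ...]  # (threshold EUR/QALY, probability)

    def probability_at(self, threshold: float) -> float:
        for lam, p in self.points:
            if lam == threshold:
                return p
        raise KeyError(f"threshold {threshold} not on the curve")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["threshold", "prob_cost_effective"])


@dataclass
class PSAResult:
    draws: list[PSADraw]
    n_failed: int
    log: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(d.index, d.delta_cost, d.delta_ly, d.delta_qaly) for d in self.draws],
            columns=["draw", "delta_cost", "delta_ly", "delta_qaly"],
        )


def _beta_draw(rng: np.random.Generator, mean: float, se: float) -> float:
    """Beta draw matched to mean/SE by moments; degenerate when se == 0."""
    if se <= 0 or mean <= 0.0 or mean >= 1.0:
        return mean
    var = min(se * se, 0.95 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _prob_beta_draw(rng: np.random.Generator, mean: float, ess: float) -> float:
    """Beta draw with the base probability as mean and an effective sample size.

    An infinite effective sample size degenerates to the mean exactly.
    """
    if mean <= 0.0 or mean >= 1.0 or math.isinf(ess):
        return mean
    return float(rng.beta(mean * ess, (1.0 - mean) * ess))


class _WeibullDrawModel:
    """Per-(arm, endpoint) Weibull sampling model for first-year probabilities.

    Means on (log shape, log scale) come from the base configuration's
    printed probabilities via :func:`calibrate_from_probs`; the covariance —
    which the trial publication does not report — is estimated once by
    fitting synthetic patient-level data of the configured size, so draws
    are centred on the base case with a trial-sized sampling uncertainty.
    """

    def __init__(
        self,
        means: Mapping[tuple[str, str], WeibullFit],
        fitted: Mapping[tuple[str, str], WeibullFit],
    ):
        self.fits = dict(means)
        self.chol: dict[tuple[str, str], np.ndarray] = {}
        for key in self.fits:
            cov = fitted[key].cov_log
            jitter = 1e-12 * np.eye(2)
            self.chol[key] = np.linalg.cholesky(cov + jitter)

    @classmethod
    def from_synthetic_ipd(cls, base: ModelConfig, n_per_arm: int, seed: int) -> "_WeibullDrawModel":
        year2 = {
            "mi": base.longterm.q_mi,
            "stroke": base.longterm.q_stroke,
            "death": base.longterm.q_cv_fatal,
        }
        means: dict[tuple[str, str], WeibullFit] = {}
        fitted: dict[tuple[str, str], WeibullFit] = {}
        for a_idx, arm_name in enumerate(("ticagrelor", "clopidogrel")):
            arm = base.arm(arm_name)
            p1 = {"mi": arm.p_mi, "stroke": arm.p_stroke, "death": arm.p_death}
            ipd = generate_ipd(
                arm, n_per_arm, seed=int(seed % (2**31 - 1)) + a_idx, longterm=base.longterm
            )
            for endpoint in ENDPOINTS:
                means[(arm_name, endpoint)] = calibrate_from_probs(p1[endpoint], year2[endpoint])
                fitted[(arm_name, endpoint)] = fit_weibull_mle(ipd, endpoint)
        return cls(means, fitted)

    def draw(
        self, rng: np.random.Generator
    ) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
        """One joint draw: per-arm first-year probabilities and common year-2 values.

        The standard-normal baseline deviate is shared between arms per
        endpoint; ticagrelor adds an independent effect deviate with equal
        weight, preserving the marginal covariance.
        """
        p1: dict[str, dict[str, float]] = {"ticagrelor": {}, "clopidogrel": {}}
        year2: dict[str, float] = {}
        for endpoint in ENDPOINTS:
            z_base = rng.standard_normal(2)
            z_eff = rng.standard_normal(2)
            for arm_name in ("clopidogrel", "ticagrelor"):
                fit = self.fits[(arm_name, endpoint)]
                z = z_base if arm_name == "clopidogrel" else (z_base + z_eff) / math.sqrt(2.0)
                theta = np.array([math.log(fit.shape), math.log(fit.scale)])
                theta = theta + self.chol[(arm_name, endpoint)] @ z
                drawn = WeibullFit(shape=math.exp(theta[0]), scale=math.exp(theta[1]))
                p1[arm_name][endpoint] = 1.0 - float(np.exp(-((1.0 / drawn.scale) ** drawn.shape)))
                if arm_name == "clopidogrel":
                    # extrapolation uses the comparator arm, as in the base model
                    year2[endpoint] = conditional_annual_prob(drawn, 2)
        return p1, year2


def _draw_document(
    spec: PSASpec,
    base: ModelConfig,
    rng: np.random.Generator,
    weibull_model: _WeibullDrawModel | None,
) -> dict:
    doc = base.model_dump(mode="json")

    # --- hazard ratios (log-normal, median-preserving) ---
    for field_name, sd in spec.hr_lognormal_sd.items():
        if sd > 0:
            base_hr = doc["hazard_ratios"][field_name]
            doc["hazard_ratios"][field_name] = base_hr * math.exp(sd * rng.standard_normal())

    # --- first-year probabilities and long-term annual probabilities ---
    if spec.weibull_draw == "covariance_mvn" and weibull_model is not None:
        p1, year2 = weibull_model.draw(rng)
        for arm_name, key in (("ticagrelor", "arm_ticagrelor"), ("clopidogrel", "arm_clopidogrel")):
            doc[key]["p_mi"] = p1[arm_name]["mi"]
            doc[key]["p_stroke"] = p1[arm_name]["stroke"]
            doc[key]["p_death"] = p1[arm_name]["death"]
        doc["longterm"]["q_mi"] = year2["mi"]
        doc["longterm"]["q_stroke"] = year2["stroke"]
        doc["longterm"]["q_cv_fatal"] = year2["death"]
    else:
        for key in ("arm_ticagrelor", "arm_clopidogrel"):
            for p_name in ("p_mi", "p_stroke", "p_death"):
                doc[key][p_name] = _prob_beta_draw(rng, doc[key][p_name], spec.beta_ess)
        for q_name in ("q_mi", "q_stroke", "q_cv_fatal"):
            doc["longterm"][q_name] = _prob_beta_draw(rng, doc["longterm"][q_name], spec.beta_ess)

    # --- utilities and decrements (beta, truncated to [0, 1] by construction) ---
    se = spec.utility_se
    for key in ("arm_ticagrelor", "arm_clopidogrel"):
        for u_name in ("u_no_event", "u_mi", "u_stroke", "u_death"):
            doc[key][u_name] = _beta_draw(rng, doc[key][u_name], se)
    for band in doc["longterm"]["u_no_event_by_age_band"]:
        doc["longterm"]["u_no_event_by_age_band"][band] = _beta_draw(
            rng, doc["longterm"]["u_no_event_by_age_band"][band], se
        )
    for du_name in ("du_stroke_y1", "du_stroke_y2plus", "du_mi_y1", "du_mi_y2plus"):
        doc["longterm"][du_name] = _beta_draw(rng, doc["longterm"][du_name], se)
    return doc


def draw_parameters(
    spec: PSASpec,
    base: ModelConfig,
    index: int,
    seed: int | None = None,
    weibull_model: _WeibullDrawModel | None = None,
) -> ModelConfig:
    """One validated parameter draw, deterministic given ``(seed, index)``.

    Invalid draws (for example first-year probabilities summing above 1) are
    redrawn up to ``spec.redraw_cap`` times before raising.
    """
    if seed is None:
        seed = base.seed
    if spec.weibull_draw == "covariance_mvn" and weibull_model is None:
        weibull_model = _WeibullDrawModel.from_synthetic_ipd(
            base, spec.ipd_n_per_arm, seed
        )
    last_error: Exception | None = None
    for attempt in range(spec.redraw_cap):
        rng = np.random.default_rng([seed, index, attempt])
        doc = _draw_document(spec, base, rng, weibull_model)
        try:
            return load_config(doc)
        except ValueError as exc:
            last_error = exc
    raise ValueError(
        f"draw {index} failed validation {spec.redraw_cap} times: {last_error}"
    )


def run_psa(
    spec: PSASpec,
    base: ModelConfig,
    life_table: LifeTable,
    seed: int | None = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Per-draw failures are logged and counted, not fatal.  Draws depend only
    on ``(seed, index)`` so results are independent of execution order.
    """
    if seed is None:
        seed = base.seed
    weibull_model = None
    if spec.weibull_draw == "covariance_mvn":
        weibull_model = _WeibullDrawModel.from_synthetic_ipd(
            base, spec.ipd_n_per_arm, seed
        )
    draws: list[PSADraw] = []
    log: list[str] = []
    n_failed = 0
    for index in range(spec.n_iterations):
        try:
            cfg = draw_parameters(spec, base, index, seed=seed, weibull_model=weibull_model)
            res = run_cea(cfg, life_table)
            draws.append(
                PSADraw(
                    index=index,
                    delta_cost=res.delta_cost,
                    delta_ly=res.delta_ly,
                    delta_qaly=res.delta_qaly,
                )
            )
        except Exception as exc:  # pragma: no cover - defensive per-draw guard
            n_failed += 1
            log.append(f"draw {index}: {exc}")
    if not draws:
        raise RuntimeError("all PSA draws failed")
    return PSAResult(draws=draws, n_failed=n_failed, log=log)


def ceac(draws: Sequence[PSADraw], thresholds: Sequence[float]) -> CEACCurve:
    """Fraction of draws with positive net monetary benefit per threshold."""
    if len(draws) == 0:
        raise ValueError("need at least one draw")
    dc = np.array([d.delta_cost for d in draws])
    dq = np.array([d.delta_qaly for d in draws])
    points = tuple(
        (float(lam), float(np.mean(lam * dq - dc > 0))) for lam in thresholds
    )
    return CEACCurve(points=points)


# ---------------------------------------------------------------------------
# deterministic scenarios


class ScenarioSpec(BaseModel):
    """A labelled set of parameter overrides applied to a base configuration.

    Overrides use dotted paths into the configuration document, for example
    ``{"costs.dtc_clopidogrel": 0.35}``; whole sub-objects may be replaced by
    passing a mapping.  ``group`` ties low/high variants of the same
    parameter together for the tornado ordering.
    """

    model_config = {"extra": "forbid"}

    label: str
    overrides: dict[str, Any] = Field(default_factory=dict)
    group: str | None = None


def apply_overrides(base: ModelConfig, overrides: Mapping[str, Any]) -> ModelConfig:
    doc = base.model_dump(mode="json")
    for path, value in overrides.items():
        parts = path.split(".")
        node = doc
        for part in parts[:-1]:
            if part not in node:
                raise KeyError(f"unknown override path {path!r}")
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(f"unknown override path {path!r}")
        if isinstance(value, Mapping) and isinstance(node[parts[-1]], dict):
            node[parts[-1]].update(dict(value))
        else:
            node[parts[-1]] = value
    return load_config(doc)


def run_scenarios(
    base: ModelConfig,
    scenarios: Sequence[ScenarioSpec],
    life_table: LifeTable,
) -> pd.DataFrame:
    """One deterministic model run per scenario; returns a tidy results table."""
    rows = []
    for sc in scenarios:
        cfg = apply_overrides(base, sc.overrides)
        res = run_cea(cfg, life_table)
        rows.append(
            {
                "scenario": sc.label,
                "group": sc.group,
                "cost_ticagrelor": res.ticagrelor.cost,
                "cost_clopidogrel": res.clopidogrel.cost,
                "ly_ticagrelor": res.ticagrelor.life_years,
                "ly_clopidogrel": res.clopidogrel.life_years,
                "qaly_ticagrelor": res.ticagrelor.qalys,
                "qaly_clopidogrel": res.clopidogrel.qalys,
                "delta_cost": res.delta_cost,
                "delta_ly": res.delta_ly,
                "delta_qaly": res.delta_qaly,
                "icer_ly": res.icer_ly,
                "icer_qaly": res.icer_qaly,
                "dominance": res.dominance.value,
            }
        )
    return pd.DataFrame(rows)


def tornado(
    base: ModelConfig,
    scenarios: Sequence[ScenarioSpec],
    life_table: LifeTable,
) -> pd.DataFrame:
    """One-way sensitivity summary: ICER range per parameter group.

    Each group's bar spans the base-case ICER and the scenario ICERs of that
    group; a dominant scenario is encoded by the ``dominant_low``/``high``
    flag with the bound clipped at zero rather than as a negative ICER.
    Rows are sorted by bar width, widest first.
    """
    base_res = run_cea(base, life_table)
    base_icer = base_res.icer_ly if base_res.icer_ly is not None else 0.0
    table = run_scenarios(base, scenarios, life_table)
    columns = ["group", "icer_low", "icer_high", "width", "dominant_bound"]
    if table.empty:
        return pd.DataFrame(columns=columns)
    rows = []
    for group, grp in table.groupby("group", dropna=True):
        values: list[float] = [base_icer]
        dominant = False
        for _, row in grp.iterrows():
            if row["dominance"] == Dominance.TICAGRELOR_DOMINANT.value:
                dominant = True
                values.append(0.0)
            elif row["icer_ly"] is not None and not pd.isna(row["icer_ly"]):
                values.append(float(row["icer_ly"]))
        low, high = min(values), max(values)
        rows.append(
            {
                "group": group,
                "icer_low": low,
                "icer_high": high,
                "width": high - low,
                "dominant_bound": dominant,
            }
        )
    out = pd.DataFrame(rows).sort_values("width", ascending=False).reset_index(drop=True)
    return out


_SCENARIO_SETS: dict[str, list[ScenarioSpec]] = {
    "paper_univariate": [
        ScenarioSpec(label="base_case", overrides={}, group=None),
        ScenarioSpec(
            label="clopidogrel_dtc_0.35",
            overrides={"costs.dtc_clopidogrel": 0.35},
            group="clopidogrel price",
        ),
        ScenarioSpec(
            label="clopidogrel_dtc_2.38",
            overrides={"costs.dtc_clopidogrel": 2.38},
            group="clopidogrel price",
        ),
        ScenarioSpec(
            label="global_model_hrs",
            overrides={"hazard_ratios": GLOBAL_MODEL_HRS.model_dump()},
            group="hazard ratios",
        ),
        ScenarioSpec(
            label="discount_0pct",
            overrides={"discount.rate_costs": 0.0, "discount.rate_effects": 0.0},
            group="discount rate",
        ),
        ScenarioSpec(
            label="discount_5pct",
            overrides={"discount.rate_costs": 0.05, "discount.rate_effects": 0.05},
            group="discount rate",
        ),
        ScenarioSpec(
            label="indirect_costs_on",
            overrides={"analysis.include_indirect_costs": True},
            group="indirect costs",
        ),
        ScenarioSpec(
            label="no_event_cost_on",
            overrides={"analysis.include_no_event_cost": True},
            group="no-event annual cost",
        ),
    ],
}


def bundled_scenario_set(name: str) -> list[ScenarioSpec]:
    try:
        return [sc.model_copy(deep=True) for sc in _SCENARIO_SETS[name]]
    except KeyError:
        raise KeyError(
            f"unknown scenario set {name!r}; available: {', '.join(sorted(_SCENARIO_SETS))}"
        ) from None
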