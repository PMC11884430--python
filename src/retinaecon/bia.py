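"""Budget impact analysis: eligible population funnel, market-share evolution,
and annual payer budgets with and without the new treatment.

The eligible population is a multiplicative epidemiological funnel
(e.g. adult population × diabetes prevalence × DME prevalence among
diabetics × share diagnosed × share treated × health coverage). Two
scenarios are compared over a base year plus three projection years: one
freezing today's market shares, one in which the new entrant gains a
fixed share increment per year while incumbents lose share proportionally
to their current shares. Per-patient annual costs come from the same cost
engine as the cost-utility analysis, with bilateral patients costed for
both eyes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .parameters import (
    ConfigSchemaError,
    ParameterSet,
    ParameterValidationError,
    Treatment,
)

__all__ = [
    "PopulationFunnel",
    "MarketScenario",
    "BIAScenario",
    "BIAResult",
    "eligible_population",
    "project_shares",
    "annual_budget",
    "per_patient_annual_cost",
    "aggregate_budget_impact",
    "run_bia",
    "load_bia_scenario",
    "save_bia_scenario",
]

_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class PopulationFunnel:
    """Base population whittled down by a chain of multiplicative fractions."""

    base_population: float
    stages: tuple[tuple[str, float], ...]  # (label, fraction) applied in order

    def __post_init__(self) -> None:
        for label, f in self.stages:
            if not 0.0 <= f <= 1.0:
                raise ParameterValidationError(f"funnel stage {label!r} fraction {f} not in [0,1]")

    @property
    def eligible(self) -> float:
        out = float(self.base_population)
        for _, f in self.stages:
            out *= f
        return out


def eligible_population(funnel: PopulationFunnel, bilateral_share: float = 0.0
                        ) -> tuple[float, float]:
    """(persons, eyes) eligible for treatment; bilateral patients add a second eye."""
    persons = funnel.eligible
    return persons, persons * (1.0 + bilateral_share)


@dataclass
class MarketScenario:
    """Treatment names, base-year shares, and the entrant's annual uptake.

    The first treatment is the new entrant. ``displacement_weights``, when
    given, override the default proportional-to-current-share rule for which
    incumbents lose share as the entrant grows.
    """

    treatments: list[str]
    base_year_shares: np.ndarray
    uptake_increment: float
    years: int = 4  # base year + 3 projection years
    displacement_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.base_year_shares = np.asarray(self.base_year_shares, dtype=float)
        if self.displacement_weights is not None:
            self.displacement_weights = np.asarray(self.displacement_weights, dtype=float)

    def validate(self) -> None:
        s = self.base_year_shares
        if s.shape != (len(self.treatments),):
            raise ParameterValidationError("one base-year share per treatment required")
        if np.any(s < 0) or np.any(s > 1):
            raise ParameterValidationError("market shares must lie in [0,1]")
        if abs(float(s.sum()) - 1.0) > _SHARE_TOL:
            raise ParameterValidationError(f"base-year shares sum to {s.sum():.12g}, not 1")
        if not 0.0 <= self.uptake_increment <= 1.0:
            raise ParameterValidationError("uptake_increment must lie in [0,1]")
        if self.years < 1:
            raise ParameterValidationError("at least the base year is required")


def project_shares(ms: MarketScenario, with_entrant: bool) -> pd.DataFrame:
    """Year-by-year market shares for one scenario (rows: years, columns: treatments).

    Without the entrant, base-year shares are frozen. With the entrant, its
    share grows by the uptake increment each post-base year (capped at 1)
    and incumbents shrink in proportion to their current shares (or per the
    configured displacement weights).
    """
    ms.validate()
    n = len(ms.treatments)
    shares = np.tile(ms.base_year_shares, (ms.years, 1))
    if with_entrant:
        for y in range(1, ms.years):
            prev = shares[y - 1].copy()
            target = min(prev[0] + ms.uptake_increment, 1.0)
            gained = target - prev[0]
            incumbents = prev[1:]
            if ms.displacement_weights is not None:
                w = ms.displacement_weights[1:].astype(float)
            else:
                w = incumbents
            total_w = w.sum()
            row = prev.copy()
            if gained > 0 and total_w > 0:
                loss = np.minimum(incumbents, gained * w / total_w)
                short = gained - loss.sum()
                if short > 1e-15:  # a weighted incumbent ran dry: spread the rest
                    remaining = incumbents - loss
                    if remaining.sum() > 0:
                        loss += np.minimum(remaining, short * remaining / remaining.sum())
                row[1:] = incumbents - loss
                row[0] = 1.0 - row[1:].sum()
            shares[y] = row
    out = pd.DataFrame(shares, columns=ms.treatments)
    out.index.name = "year_offset"
    return out


def annual_budget(persons: float, shares, per_patient_annual_cost) -> float:
    """Payer budget for one year: Σ persons × share × per-patient cost."""
    shares = pd.Series(shares)
    costs = pd.Series(per_patient_annual_cost)
    if abs(float(shares.sum()) - 1.0) > _SHARE_TOL:
        raise ParameterValidationError(f"shares sum to {shares.sum():.12g}, not 1")
    missing = set(shares.index) - set(costs.index)
    if missing:
        raise ParameterValidationError(f"no per-patient cost for treatments {sorted(missing)}")
    return float((persons * shares * costs[shares.index]).sum())


def per_patient_annual_cost(ps: ParameterSet, treatment: Treatment | str,
                            bilateral_share: float) -> dict[str, float]:
    """Per-patient first-year cost components from the cost-utility engine.

    Loading-phase (year-1) injection schedule times drug plus visit costs;
    bilateral patients are injected in both eyes, with the second eye's
    visit charged the configured administration share. Supportive care
    accrues on the baseline mass whose better eye is at or past the
    threshold; adverse-event management accrues on everyone.
    """
    if isinstance(treatment, str):
        treatment = next(t for t in ps.treatments if t.name == treatment)
    inj = treatment.injections_year1
    visit = treatment.admin_cost_per_injection + treatment.monitoring_cost_per_visit
    drug = inj * (1.0 + bilateral_share) * treatment.drug_cost_per_injection
    admin = inj * visit + bilateral_share * inj * ps.bilateral.second_eye_admin_share * visit
    impaired = float(ps.baseline_va_distribution_first_eye[ps.supportive.threshold_state:].sum())
    supportive = ps.supportive.annual_cost * impaired
    ae = ps.settings.ae_cost_per_cycle * ps.settings.cycles_per_year
    return {"drug": drug, "admin": admin, "supportive": supportive, "ae": ae,
            "total": drug + admin + supportive + ae}


@dataclass
class BIAResult:
    """Per-year budgets for both scenarios, impacts, and the 3-year cumulative totals."""

    table: pd.DataFrame  # rows: without, with, impact; columns: years
    cumulative_without: float
    cumulative_with: float
    cumulative_impact: float
    component_split: pd.DataFrame | None = None  # cumulative impact by cost component

    @property
    def impact_by_year(self) -> pd.Series:
        return self.table.loc["impact"]


def aggregate_budget_impact(years, without_budgets, with_budgets) -> BIAResult:
    """Assemble the scenario table and cumulative totals from annual budgets.

    The budget impact is (with − without) per year; cumulative totals sum
    the post-base years only, computed from unrounded values.
    """
    years = list(years)
    wo = np.asarray(without_budgets, dtype=float)
    wi = np.asarray(with_budgets, dtype=float)
    if not (len(years) == wo.size == wi.size):
        raise ParameterValidationError("years and budget series must have equal length")
    impact = wi - wo
    table = pd.DataFrame([wo, wi, impact], index=["without", "with", "impact"], columns=years)
    return BIAResult(
        table=table,
        cumulative_without=float(wo[1:].sum()),
        cumulative_with=float(wi[1:].sum()),
        cumulative_impact=float(impact[1:].sum()),
    )


@dataclass
class BIAScenario:
    """A complete budget-impact input: funnel, market evolution, unit costs."""

    disease: str
    funnel: PopulationFunnel
    market: MarketScenario
    costs: dict[str, dict[str, float]]
    bilateral_share: float = 0.0
    population_growth_rate: float = 0.0
    base_year: int = 2024

    def validate(self) -> "BIAScenario":
        self.market.validate()
        if not 0 <= self.bilateral_share <= 1:
            raise ParameterValidationError("bilateral_share must lie in [0,1]")
        missing = set(self.market.treatments) - set(self.costs)
        if missing:
            raise ParameterValidationError(f"no cost entry for treatments {sorted(missing)}")
        return self

    def run(self) -> "BIAResult":
        return run_bia(self.funnel, self.market, self.costs, self.bilateral_share,
                       self.population_growth_rate, self.base_year)


def save_bia_scenario(sc: BIAScenario, path: str) -> str:
    sc.validate()
    doc = {
        "schema_version": 1,
        "disease": sc.disease,
        "funnel": {
            "base_population": float(sc.funnel.base_population),
            "stages": [{"label": lab, "fraction": float(f)} for lab, f in sc.funnel.stages],
        },
        "bilateral_share": float(sc.bilateral_share),
        "market": {
            "treatments": list(sc.market.treatments),
            "base_year_shares": [float(x) for x in sc.market.base_year_shares],
            "uptake_increment": float(sc.market.uptake_increment),
            "years": int(sc.market.years),
        },
        "costs": {k: {c: float(v) for c, v in d.items()} for k, d in sc.costs.items()},
        "population_growth_rate": float(sc.population_growth_rate),
        "base_year": int(sc.base_year),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)
    return path


def load_bia_scenario(path: str) -> BIAScenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigSchemaError(f"{path}: BIA scenario file must be a mapping")
    try:
        funnel = PopulationFunnel(
            base_population=doc["funnel"]["base_population"],
            stages=tuple((s["label"], s["fraction"]) for s in doc["funnel"]["stages"]),
        )
        market = MarketScenario(
            treatments=list(doc["market"]["treatments"]),
            base_year_shares=doc["market"]["base_year_shares"],
            uptake_increment=doc["market"]["uptake_increment"],
            years=doc["market"].get("years", 4),
        )
        sc = BIAScenario(
            disease=doc["disease"],
            funnel=funnel,
            market=market,
            costs=doc["costs"],
            bilateral_share=doc.get("bilateral_share", 0.0),
            population_growth_rate=doc.get("population_growth_rate", 0.0),
            base_year=doc.get("base_year", 2024),
        )
    except KeyError as e:
        raise ConfigSchemaError(f"{path}: missing required key {e.args[0]!r}") from None
    return sc.validate()


def run_bia(
    funnel: PopulationFunnel,
    market: MarketScenario,
    costs: dict[str, dict[str, float]],
    bilateral_share: float = 0.0,
    population_growth_rate: float = 0.0,
    base_year: int = 2024,
) -> BIAResult:
    """Full budget impact analysis for one disease.

    ``costs`` maps each treatment to its per-patient annual cost components
    (at least a ``total``; ``drug`` and ``admin`` enable the component
    split of the savings). The eligible population may grow by a constant
    annual rate over the projection years.
    """
    market.validate()
    missing = set(market.treatments) - set(costs)
    if missing:
        raise ParameterValidationError(f"no cost entry for treatments {sorted(missing)}")
    persons0, _ = eligible_population(funnel, bilateral_share)
    years = [base_year + y for y in range(market.years)]
    persons = [persons0 * (1.0 + population_growth_rate) ** y for y in range(market.years)]
    shares_wo = project_shares(market, with_entrant=False)
    shares_wi = project_shares(market, with_entrant=True)

    def budgets(shares: pd.DataFrame, component: str) -> list[float]:
        comp_costs = {t: costs[t].get(component, 0.0) for t in market.treatments}
        return [annual_budget(persons[y], shares.iloc[y], comp_costs)
                for y in range(market.years)]

    res = aggregate_budget_impact(years, budgets(shares_wo, "total"), budgets(shares_wi, "total"))
    split_rows = {}
    for component in ("drug", "admin"):
        if all(component in costs[t] for t in market.treatments):
            wo = np.asarray(budgets(shares_wo, component))
            wi = np.asarray(budgets(shares_wi, component))
            split_rows[component] = float((wi - wo)[1:].sum())
    if split_rows:
        res.component_split = pd.DataFrame(
            {"cumulative_impact": split_rows}
        ).rename_axis("component")
    return res
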