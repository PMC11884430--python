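"""Discounted QALY and cost accounting over a cohort trajectory.

Utilities use the better-seeing-eye convention: a person's quality of life
is driven by whichever eye sees better, with the two eyes coupled as
independent marginals. An unaffected fellow eye is assumed to see well
(best state), so quality of life only degrades once disease is bilateral
or the affected eye is the better one. Costs split into the four
components reported by cost-utility analyses of anti-VEGF therapy: drug
acquisition, administration (including monitoring visits), adverse-event
management, and supportive care for visual impairment.

No half-cycle correction is applied by default: cycle 1 is undiscounted
and events are costed at cycle start, which makes constant flows match
the geometric series exactly. A half-cycle option is available via
``EconomicSettings.half_cycle_correction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import CohortState, Trajectory, run_cohort
from .parameters import (
    N_STATES,
    BilateralInputs,
    EconomicSettings,
    ParameterSet,
    SupportiveCare,
    Treatment,
    UtilityModel,
)

__all__ = [
    "CostComponents",
    "EconResult",
    "discount_factor",
    "cycle_utility",
    "cycle_costs",
    "accumulate",
    "evaluate",
]

CYCLE_YEARS = 4.0 / 52.0  # one 4-week cycle as a fraction of a year


def discount_factor(cycle: int, annual_rate: float, cycles_per_year: int = 13,
                    half_cycle: bool = False) -> float:
    """Present-value factor for a 1-based cycle; cycle 1 is undiscounted."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    offset = 0.5 if half_cycle else 0.0
    return float((1.0 + annual_rate) ** (-(cycle - 1 + offset) / cycles_per_year))


def _better_eye_distribution(state: CohortState) -> np.ndarray:
    """Mass over the better-seeing eye's state (index = min of the two eyes).

    Within each treatment-status compartment the two eyes are independent
    marginals; the unaffected second-eye pool counts as best-state vision.
    """
    out = np.zeros(N_STATES)
    for first, second, unaff in (
        (state.first_on, state.second_on, state.unaffected_on),
        (state.first_off, state.second_off, state.unaffected_off),
    ):
        persons = float(first.sum())
        if persons <= 0:
            continue
        p = first / persons  # first-eye state distribution
        affected = float(second.sum())
        # unaffected fellow eye sees best: better eye is state 0
        out[0] += unaff
        if affected > 0:
            q = second / affected
            # P(min(i,j) = k) under independence
            pc = np.concatenate([np.cumsum(p[::-1])[::-1], [0.0]])  # P(i >= k)
            qc = np.concatenate([np.cumsum(q[::-1])[::-1], [0.0]])
            both_ge = pc[:-1] * qc[:-1]
            min_ge = both_ge
            min_k = min_ge - np.append(pc[1:-1] * qc[1:-1], 0.0)
            out += affected * min_k
    return out


def cycle_utility(state: CohortState, um: UtilityModel, injections: float) -> float:
    """One cycle's QALY contribution for the cohort, at cycle start.

    Better-seeing-eye utility times 4/52 of a year, minus the per-injection
    disutility for every injection administered this cycle.
    """
    better = _better_eye_distribution(state)
    u = float(better @ um.state_utilities) * CYCLE_YEARS
    return u - injections * um.injection_disutility


@dataclass(frozen=True)
class CostComponents:
    """One cycle's undiscounted cost, split into the four reported components."""

    drug: float
    admin: float
    ae: float
    supportive: float

    @property
    def total(self) -> float:
        return self.drug + self.admin + self.ae + self.supportive


def cycle_costs(
    state: CohortState,
    treatment: Treatment,
    supportive: SupportiveCare,
    settings: EconomicSettings,
    bilateral: BilateralInputs,
    injections: float,
    injections_second_eye: float | None = None,
) -> CostComponents:
    """One cycle's cost components at cycle start.

    Drug cost is charged in full per injection for either eye. Administration
    (procedure + monitoring visit) is charged in full for first-eye
    injections; second-eye injections are charged the configured share, since
    both eyes are treated in the same visit. Supportive care accrues on the
    mass whose better-seeing eye is at or past the threshold state, spread
    uniformly over the 13 cycles of a year; adverse-event management accrues
    on all alive mass identically across treatments.
    """
    if injections_second_eye is None:
        on_mass = state.first_on.sum()
        s = state.second_on.sum() / on_mass if on_mass > 0 else 0.0
        injections_second_eye = injections * s / (1.0 + s) if s > 0 else 0.0
    inj_first = injections - injections_second_eye
    visit_cost = treatment.admin_cost_per_injection + treatment.monitoring_cost_per_visit
    drug = injections * treatment.drug_cost_per_injection
    admin = inj_first * visit_cost + injections_second_eye * bilateral.second_eye_admin_share * visit_cost
    better = _better_eye_distribution(state)
    impaired = float(better[supportive.threshold_state:].sum())
    supportive_cost = supportive.annual_cost / settings.cycles_per_year * impaired
    ae = settings.ae_cost_per_cycle * state.alive
    return CostComponents(drug=float(drug), admin=float(admin), ae=float(ae),
                          supportive=float(supportive_cost))


@dataclass
class EconResult:
    """Discounted totals of a cohort run, with undiscounted variants and per-cycle detail."""

    treatment: str
    qalys: float
    drug_cost: float
    admin_cost: float
    ae_cost: float
    supportive_cost: float
    qalys_undiscounted: float
    drug_cost_undiscounted: float
    admin_cost_undiscounted: float
    ae_cost_undiscounted: float
    supportive_cost_undiscounted: float
    total_injections: float
    per_cycle: pd.DataFrame = field(repr=False, default=None)

    @property
    def total_cost(self) -> float:
        return self.drug_cost + self.admin_cost + self.ae_cost + self.supportive_cost

    @property
    def total_cost_undiscounted(self) -> float:
        return (self.drug_cost_undiscounted + self.admin_cost_undiscounted
                + self.ae_cost_undiscounted + self.supportive_cost_undiscounted)

    def components_row(self) -> dict[str, float]:
        """Cost/QALY components shaped like a published component table."""
        return {
            "treatment": self.treatment,
            "drug_cost": self.drug_cost,
            "admin_cost": self.admin_cost,
            "ae_cost": self.ae_cost,
            "supportive_cost": self.supportive_cost,
            "total_cost": self.total_cost,
            "qalys": self.qalys,
            "injections": self.total_injections,
        }


def accumulate(traj: Trajectory, ps: ParameterSet, treatment: Treatment | None = None) -> EconResult:
    """Sum discounted per-cycle utilities and cost components over the horizon."""
    if treatment is None:
        treatment = next(t for t in ps.treatments if t.name == traj.treatment)
    if len(traj) != ps.settings.total_cycles:
        raise ValueError(
            f"trajectory has {len(traj)} cycles but the settings specify {ps.settings.total_cycles}"
        )
    s = ps.settings
    rows = []
    for rec in traj:
        df_c = discount_factor(rec.cycle, s.discount_rate_costs, s.cycles_per_year,
                               s.half_cycle_correction)
        df_e = discount_factor(rec.cycle, s.discount_rate_effects, s.cycles_per_year,
                               s.half_cycle_correction)
        comp = cycle_costs(rec.state, treatment, ps.supportive, s, ps.bilateral,
                           rec.injections, rec.injections_second_eye)
        util = cycle_utility(rec.state, ps.utilities, rec.injections)
        rows.append((rec.cycle, rec.phase.value, util, comp.drug, comp.admin, comp.ae,
                     comp.supportive, rec.injections, df_c, df_e))
    per_cycle = pd.DataFrame(
        rows, columns=["cycle", "phase", "utility", "drug", "admin", "ae", "supportive",
                       "injections", "df_cost", "df_effect"],
    )
    disc = lambda col: float((per_cycle[col] * per_cycle["df_cost"]).sum())
    return EconResult(
        treatment=traj.treatment,
        qalys=float((per_cycle["utility"] * per_cycle["df_effect"]).sum()),
        drug_cost=disc("drug"),
        admin_cost=disc("admin"),
        ae_cost=disc("ae"),
        supportive_cost=disc("supportive"),
        qalys_undiscounted=float(per_cycle["utility"].sum()),
        drug_cost_undiscounted=float(per_cycle["drug"].sum()),
        admin_cost_undiscounted=float(per_cycle["admin"].sum()),
        ae_cost_undiscounted=float(per_cycle["ae"].sum()),
        supportive_cost_undiscounted=float(per_cycle["supportive"].sum()),
        total_injections=float(per_cycle["injections"].sum()),
        per_cycle=per_cycle,
    )


def evaluate(ps: ParameterSet, treatment: Treatment | str | None = None) -> EconResult:
    """Convenience: run the cohort and accumulate outcomes in one call."""
    traj = run_cohort(ps, treatment)
    t = next(t for t in ps.treatments if t.name == traj.treatment)
    return accumulate(traj, ps, t)
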