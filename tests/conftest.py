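"""Shared fixtures: synthetic scenarios and analytically tractable toy scenarios."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from retinaecon import (
    BilateralInputs,
    EconomicSettings,
    ParameterSet,
    PhaseTag,
    SupportiveCare,
    SyntheticSpec,
    TransitionMatrix,
    Treatment,
    UtilityModel,
    default_states,
    generate_parameter_set,
)


def identity_matrices() -> dict[PhaseTag, list[TransitionMatrix]]:
    """Stay-put dynamics, legal in every phase (the zero-movement is always allowed)."""
    return {tag: [TransitionMatrix(tag, np.eye(6))] for tag in PhaseTag}


def make_toy_ps(
    horizon_years: int = 2,
    utilities=(1.0,) * 6,
    injections=(13.0, 13.0, 13.0),
    comparator_extra_injections: float = 0.0,
    drug_cost: float = 100.0,
    admin_cost: float = 0.0,
    monitoring_cost: float = 0.0,
    supportive_annual: float = 0.0,
    ae_cost_per_cycle: float = 0.0,
    discount: float = 0.0,
    discontinuation_fraction: float = 0.0,
    injection_disutility: float = 0.0,
    baseline=(1.0, 0, 0, 0, 0, 0),
    bilateral=BilateralInputs(0.0, 0.0, 0.5),
    mortality: float = 0.0,
) -> ParameterSet:
    """A deliberately degenerate scenario (identity dynamics, optional zero
    bilateral disease) whose outcomes have closed forms."""

    def treat(name: str, extra: float) -> Treatment:
        return Treatment(
            name=name,
            injections_year1=injections[0] + extra,
            injections_year2=injections[1] + extra,
            injections_year3plus=injections[2] + extra,
            drug_cost_per_injection=drug_cost,
            admin_cost_per_injection=admin_cost,
            monitoring_cost_per_visit=monitoring_cost,
            matrices=identity_matrices(),
        )

    ps = ParameterSet(
        disease="DME",
        states=default_states(),
        baseline_va_distribution_first_eye=np.asarray(baseline, dtype=float),
        baseline_va_distribution_second_eye=np.asarray(baseline, dtype=float),
        treatments=[treat("intervention", 0.0), treat("comparator", comparator_extra_injections)],
        utilities=UtilityModel(np.asarray(utilities, dtype=float),
                               injection_disutility=injection_disutility),
        supportive=SupportiveCare(threshold_state=4, annual_cost=supportive_annual),
        bilateral=bilateral,
        settings=EconomicSettings(
            horizon_years=horizon_years,
            discount_rate_costs=discount,
            discount_rate_effects=discount,
            discontinuation_fraction=discontinuation_fraction,
            ae_cost_per_cycle=ae_cost_per_cycle,
            mortality_annual_prob=mortality,
        ),
    )
    return ps.validate()


def with_settings(ps: ParameterSet, **overrides) -> ParameterSet:
    """Copy of ``ps`` with replaced economic settings, revalidated."""
    import copy

    new = copy.deepcopy(ps)
    new.settings = dataclasses.replace(ps.settings, **overrides)
    return new.validate()


@pytest.fixture(scope="session")
def dme_ps() -> ParameterSet:
    """A 2-treatment synthetic DME-like scenario at the full 25-year horizon."""
    return generate_parameter_set(SyntheticSpec(disease="DME", n_treatments=2, seed=11))


@pytest.fixture(scope="session")
def short_ps() -> ParameterSet:
    """A 3-year version of the synthetic scenario, spanning all three phases."""
    ps = generate_parameter_set(SyntheticSpec(disease="DME", n_treatments=2, seed=11))
    return with_settings(ps, horizon_years=3)
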