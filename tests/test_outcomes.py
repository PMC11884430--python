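"""Discounting, better-seeing-eye utility, cost components and accumulation."""

import numpy as np
import pytest

from retinaecon import CohortState, discount_factor, run_cohort, accumulate, evaluate
from retinaecon.outcomes import CYCLE_YEARS, _better_eye_distribution, cycle_costs, cycle_utility
from retinaecon.parameters import (
    BilateralInputs,
    EconomicSettings,
    SupportiveCare,
    UtilityModel,
)

from conftest import make_toy_ps, with_settings


def _state(first, second=None, unaffected=None):
    """CohortState with all mass on treatment; second defaults to unaffected."""
    first = np.asarray(first, dtype=float)
    if second is None:
        second = np.zeros(6)
        unaffected = first.sum() if unaffected is None else unaffected
    else:
        second = np.asarray(second, dtype=float)
        unaffected = (first.sum() - second.sum()) if unaffected is None else unaffected
    return CohortState(
        first_on=first, first_off=np.zeros(6),
        second_on=second, second_off=np.zeros(6),
        unaffected_on=float(unaffected), unaffected_off=0.0,
    )


class TestDiscountFactor:
    def test_first_cycle_undiscounted(self):
        assert discount_factor(1, 0.05) == 1.0

    def test_one_year_later_closed_form(self):
        assert discount_factor(14, 0.05) == pytest.approx(1 / 1.05, abs=1e-12)

    def test_zero_rate_never_discounts(self):
        assert all(discount_factor(c, 0.0) == 1.0 for c in (1, 50, 325))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestCycleUtility:
    def test_degenerate_best_state_both_eyes(self):
        um = UtilityModel(np.array([0.85, 0.8, 0.7, 0.6, 0.5, 0.4]))
        s = _state([1, 0, 0, 0, 0, 0], second=[1, 0, 0, 0, 0, 0])
        assert cycle_utility(s, um, 0.0) == pytest.approx(0.85 * 4 / 52)

    def test_uniform_utilities_independent_of_distribution(self):
        um = UtilityModel(np.full(6, 0.7))
        rng = np.random.default_rng(3)
        s = _state(rng.dirichlet(np.ones(6)), second=None)
        assert cycle_utility(s, um, 0.0) == pytest.approx(0.7 * 4 / 52)

    def test_matches_brute_force_over_eye_pairs(self):
        """Better-seeing-eye utility equals the 36-pair sum taking the better
        (lower-index) eye, with unaffected fellow eyes counted as best vision."""
        rng = np.random.default_rng(7)
        u = np.sort(rng.uniform(0.3, 0.9, 6))[::-1]
        um = UtilityModel(u.copy())
        p = rng.dirichlet(np.ones(6))
        affected = 0.6
        q = rng.dirichlet(np.ones(6)) * affected
        s = _state(p, second=q, unaffected=1 - affected)
        brute = (1 - affected) * u[0]  # unaffected fellow eye: better eye is state 0
        for i in range(6):
            for j in range(6):
                brute += p[i] * q[j] * u[min(i, j)]
        assert cycle_utility(s, um, 0.0) == pytest.approx(brute * 4 / 52, abs=1e-12)

    def test_injection_disutility_subtracts(self):
        um = UtilityModel(np.full(6, 0.8), injection_disutility=0.001)
        s = _state([1, 0, 0, 0, 0, 0])
        base = cycle_utility(s, um, 0.0)
        assert cycle_utility(s, um, 2.0) == pytest.approx(base - 0.002)


class TestCycleCosts:
    def _fixtures(self):
        ps = make_toy_ps(drug_cost=800.0, admin_cost=60.0, monitoring_cost=40.0,
                         supportive_annual=1300.0, ae_cost_per_cycle=5.0)
        return ps.intervention, ps.supportive, ps.settings, ps.bilateral

    def test_zero_injections_only_ae_cost(self):
        t, supp, settings, bil = self._fixtures()
        s = _state([1, 0, 0, 0, 0, 0])
        c = cycle_costs(s, t, supp, settings, bil, injections=0.0)
        assert c.drug == 0 and c.admin == 0 and c.supportive == 0
        assert c.ae == pytest.approx(5.0)

    def test_one_injection_charges_drug_cost(self):
        t, supp, settings, bil = self._fixtures()
        s = _state([1, 0, 0, 0, 0, 0])
        c = cycle_costs(s, t, supp, settings, bil, injections=1.0, injections_second_eye=0.0)
        assert c.drug == pytest.approx(800.0)
        assert c.admin == pytest.approx(100.0)  # admin 60 + monitoring 40

    def test_supportive_hand_arithmetic(self):
        """Mass 0.2 with the better eye at/past state 4, annual aids 1300:
        1300 x 0.2 / 13 = 20 per cycle."""
        t, supp, settings, bil = self._fixtures()
        first = np.array([0.3, 0.5, 0, 0, 0.1, 0.1])
        worst_second = np.zeros(6); worst_second[5] = 1.0
        s = _state(first, second=worst_second, unaffected=0.0)
        c = cycle_costs(s, t, supp, settings, bil, injections=0.0)
        assert c.supportive == pytest.approx(1300 * 0.2 / 13)

    def test_second_eye_visit_share(self):
        t, supp, settings, bil = self._fixtures()  # share 0.5
        s = _state([1, 0, 0, 0, 0, 0], second=[1, 0, 0, 0, 0, 0])
        c = cycle_costs(s, t, supp, settings, bil, injections=2.0, injections_second_eye=1.0)
        assert c.drug == pytest.approx(1600.0)  # both eyes pay full drug cost
        assert c.admin == pytest.approx(100.0 + 0.5 * 100.0)


class TestAccumulate:
    def test_full_health_no_discounting_gives_horizon_qalys(self):
        ps = make_toy_ps(horizon_years=25, utilities=(1.0,) * 6, injections=(0, 0, 0))
        res = evaluate(ps, ps.intervention)
        assert res.qalys == pytest.approx(25.0, abs=1e-9)

    def test_constant_cost_matches_geometric_series(self):
        """Constant per-cycle flows discount to the closed-form geometric sum."""
        ps = make_toy_ps(horizon_years=25, injections=(13.0, 13.0, 13.0),
                         drug_cost=100.0, discount=0.05)
        res = evaluate(ps, ps.intervention)
        cycles = np.arange(1, 326)
        series = float((100.0 * 1.05 ** (-(cycles - 1) / 13)).sum())
        assert res.drug_cost == pytest.approx(series, abs=1e-9)

    def test_total_cost_additivity(self, dme_ps):
        res = evaluate(dme_ps, dme_ps.intervention)
        assert res.total_cost == pytest.approx(
            res.drug_cost + res.admin_cost + res.ae_cost + res.supportive_cost, abs=1e-6)

    def test_discounted_totals_decrease_with_rate(self, short_ps):
        results = [evaluate(with_settings(short_ps, discount_rate_costs=r,
                                          discount_rate_effects=r), "intervention")
                   for r in (0.0, 0.05, 0.10)]
        costs = [r.total_cost for r in results]
        qalys = [r.qalys for r in results]
        assert costs[0] > costs[1] > costs[2]
        assert qalys[0] > qalys[1] > qalys[2]
        for r in results[1:]:
            assert r.total_cost <= results[0].total_cost_undiscounted

    def test_qalys_monotone_in_state_utilities(self, short_ps):
        import copy

        better = copy.deepcopy(short_ps)
        better.utilities.state_utilities = short_ps.utilities.state_utilities + 0.02
        assert evaluate(better, "intervention").qalys > evaluate(short_ps, "intervention").qalys

    def test_drug_and_admin_scale_linearly_with_schedule(self):
        ps1 = make_toy_ps(horizon_years=3, injections=(6, 4, 3), drug_cost=500.0,
                          admin_cost=50.0, monitoring_cost=25.0)
        ps2 = make_toy_ps(horizon_years=3, injections=(12, 8, 6), drug_cost=500.0,
                          admin_cost=50.0, monitoring_cost=25.0)
        r1, r2 = evaluate(ps1, "intervention"), evaluate(ps2, "intervention")
        assert r2.drug_cost == pytest.approx(2 * r1.drug_cost, rel=1e-12)
        assert r2.admin_cost == pytest.approx(2 * r1.admin_cost, rel=1e-12)

    def test_horizon_mismatch_rejected(self, short_ps):
        traj = run_cohort(short_ps, short_ps.intervention)
        longer = with_settings(short_ps, horizon_years=4)
        with pytest.raises(ValueError, match="cycles"):
            accumulate(traj, longer, longer.intervention)

    def test_better_eye_distribution_is_probability_vector(self, dme_ps):
        traj = run_cohort(dme_ps, dme_ps.intervention)
        for rec in traj.records[::25]:
            d = _better_eye_distribution(rec.state)
            assert np.all(d >= -1e-12)
            assert d.sum() == pytest.approx(rec.state.alive, abs=1e-9)
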