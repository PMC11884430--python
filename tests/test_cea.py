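"""Incremental analysis, dominance labels, DSA bounds/tornado, PSA and CEAC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retinaecon import (
    DSABound,
    PSAEntry,
    PSASpec,
    ceac,
    derive_bounds,
    evaluate,
    incremental_analysis,
    run_dsa,
    run_psa,
    sample_parameters,
)
from retinaecon.cea import full_cea
from retinaecon.outcomes import EconResult
from retinaecon.parameters import get_path

from conftest import make_toy_ps


def econ(name: str, cost: float, qalys: float) -> EconResult:
    """A minimal EconResult carrying given totals (all cost in the drug slot)."""
    return EconResult(
        treatment=name, qalys=qalys, drug_cost=cost, admin_cost=0.0, ae_cost=0.0,
        supportive_cost=0.0, qalys_undiscounted=qalys, drug_cost_undiscounted=cost,
        admin_cost_undiscounted=0.0, ae_cost_undiscounted=0.0,
        supportive_cost_undiscounted=0.0, total_injections=0.0,
    )


class TestIncrementalAnalysis:
    def test_cheaper_and_better_is_dominant(self):
        # published-table readoff: intervention 17857/7.94 vs comparator 21706/7.73
        inc = incremental_analysis(econ("faricimab", 17857, 7.94),
                                   econ("aflibercept", 21706, 7.73), wtp=5988)
        assert inc.delta_cost == pytest.approx(3849)
        assert inc.delta_qaly == pytest.approx(0.21)
        assert inc.label == "dominant" and inc.icer is None

    def test_trade_off_quadrant_icer_and_nmb(self):
        # intervention dearer by 1000 but gains 0.5 QALYs at WTP 5988
        inc = incremental_analysis(econ("a", 11000, 5.5), econ("b", 10000, 5.0), wtp=5988)
        assert inc.delta_cost == -1000 and inc.delta_qaly == 0.5
        assert inc.nmb == pytest.approx(5988 * 0.5 - 1000)  # 1994
        assert inc.icer == pytest.approx(2000)
        assert inc.label == "more effective, costlier"

    def test_identical_results_are_equivalent(self):
        inc = incremental_analysis(econ("a", 100, 1.0), econ("b", 100, 1.0), wtp=5000)
        assert inc.delta_cost == 0 and inc.delta_qaly == 0 and inc.nmb == 0
        assert inc.label == "equivalent"

    def test_equal_effect_label_follows_cost_sign(self):
        inc = incremental_analysis(econ("a", 90, 1.0), econ("b", 100, 1.0), wtp=5000)
        assert inc.icer is None and inc.label == "equal effect, cheaper"

    @pytest.mark.parametrize("seed", range(30))
    def test_labels_match_brute_force_quadrants(self, seed):
        rng = np.random.default_rng(seed)
        dc, dq = rng.normal(0, 1000), rng.normal(0, 0.5)
        inc = incremental_analysis(econ("i", 10000, 5 + dq), econ("c", 10000 + dc, 5.0), 5988)
        if dq > 0 and dc > 0:
            assert inc.label == "dominant"
        elif dq < 0 and dc < 0:
            assert inc.label == "dominated"
        else:
            assert inc.label not in ("dominant", "dominated")
        assert inc.nmb == pytest.approx(5988 * dq + dc, abs=1e-6)


class TestDeriveBounds:
    def test_reported_ci_passes_through(self):
        ps = make_toy_ps()
        spec = PSASpec(entries=[PSAEntry("settings.ae_cost_per_cycle", "normal",
                                         {"mu": 10.0, "sigma": 2.0}, ci=(7.0, 13.0))])
        (b,) = derive_bounds(ps, spec)
        assert (b.low, b.high, b.rule) == (7.0, 13.0, "CI95")

    def test_percentiles_match_statistics_library(self):
        ps = make_toy_ps(supportive_annual=100.0)
        g = stats.gamma(25.0, scale=4.0)  # mean 100
        spec = PSASpec(entries=[PSAEntry("supportive.annual_cost", "gamma",
                                         {"shape": 25.0, "scale": 4.0})])
        (b,) = derive_bounds(ps, spec)
        assert b.low == pytest.approx(g.ppf(0.30))
        assert b.high == pytest.approx(g.ppf(0.70))
        assert b.rule == "P30_P70"

    def test_drug_costs_always_plus_minus_ten_percent(self):
        ps = make_toy_ps(drug_cost=800.0)
        spec = PSASpec(entries=[PSAEntry("treatments[0].drug_cost_per_injection", "gamma",
                                         {"shape": 100.0, "scale": 8.0}, ci=(700.0, 900.0))])
        (b,) = derive_bounds(ps, spec)
        assert b.low == pytest.approx(720.0)
        assert b.high == pytest.approx(880.0)


class TestRunDSA:
    def test_treatment_neutral_parameter_has_zero_swing(self):
        # adverse-event cost hits both arms identically and cancels in the NMB
        ps = make_toy_ps(horizon_years=2, comparator_extra_injections=2.0,
                         ae_cost_per_cycle=5.0, injection_disutility=0.001)
        table = run_dsa(ps, [DSABound("settings.ae_cost_per_cycle", 1.0, 10.0, "P30_P70")])
        assert table.loc[0, "swing"] == pytest.approx(0.0, abs=1e-9)

    def test_comparator_drug_cost_dominates_tornado(self):
        ps = make_toy_ps(horizon_years=2, comparator_extra_injections=4.0,
                         drug_cost=1000.0, ae_cost_per_cycle=2.0,
                         injection_disutility=0.001)
        bounds = [
            DSABound("treatments[1].drug_cost_per_injection", 900.0, 1100.0, "PCT10"),
            DSABound("settings.ae_cost_per_cycle", 1.8, 2.2, "P30_P70"),
            DSABound("utilities.injection_disutility", 0.0009, 0.0011, "P30_P70"),
        ]
        table = run_dsa(ps, bounds)
        assert table.loc[0, "parameter"] == "treatments[1].drug_cost_per_injection"

    def test_unresolvable_parameter_raises_config_error(self):
        from retinaecon.parameters import ConfigSchemaError

        ps = make_toy_ps()
        with pytest.raises(ConfigSchemaError):
            run_dsa(ps, [DSABound("treatments[0].phantom", 0.0, 1.0, "CI95")])


class TestSampleParameters:
    def _degenerate_spec(self, base=800.0):
        return PSASpec(entries=[PSAEntry("treatments[0].drug_cost_per_injection",
                                         "normal", {"mu": base, "sigma": 0.0})],
                       n_draws=10, seed=5)

    def test_degenerate_distributions_return_base(self):
        ps = make_toy_ps(drug_cost=800.0)
        drawn = sample_parameters(self._degenerate_spec(), ps, 3)
        assert get_path(drawn, "treatments[0].drug_cost_per_injection") == pytest.approx(800.0)

    def test_same_seed_and_index_reproduce_draw(self):
        ps = make_toy_ps(drug_cost=800.0)
        spec = PSASpec(entries=[PSAEntry("treatments[0].drug_cost_per_injection",
                                         "gamma", {"shape": 100.0, "scale": 8.0})],
                       n_draws=10, seed=5)
        a = sample_parameters(spec, ps, 4)
        b = sample_parameters(spec, ps, 4)
        assert a == b
        c = sample_parameters(spec, ps, 5)
        assert get_path(a, "treatments[0].drug_cost_per_injection") != \
            get_path(c, "treatments[0].drug_cost_per_injection")

    def test_gamma_sampling_recovers_configured_mean(self):
        entry = PSAEntry("x", "gamma", {"shape": 100.0, "scale": 8.0})  # mean 800, sd 80
        rng = np.random.default_rng(11)
        draws = np.array([entry.sample(rng) for _ in range(10_000)])
        se = 80 / np.sqrt(10_000)
        assert abs(draws.mean() - 800.0) < 3 * se

    def test_matrix_rows_renormalised_and_phase_legal(self, short_ps):
        spec = PSASpec(entries=[], n_draws=4, seed=1, matrix_logit_sd=0.3)
        drawn = sample_parameters(spec, short_ps, 0)
        drawn.validate()  # row sums and phase masks intact
        base = short_ps.treatments[0].matrices
        new = drawn.treatments[0].matrices
        tag = list(base)[0]
        assert not np.allclose(base[tag][0].probs, new[tag][0].probs)


class TestRunPSA:
    def test_degenerate_spec_reproduces_deterministic_result(self):
        ps = make_toy_ps(horizon_years=2, comparator_extra_injections=2.0)
        spec = PSASpec(entries=[PSAEntry("treatments[0].drug_cost_per_injection",
                                         "normal", {"mu": 100.0, "sigma": 0.0})],
                       n_draws=3, seed=0)
        res = run_psa(ps, spec)
        det = evaluate(ps, ps.intervention)
        for _, row in res.draws[res.draws.treatment == "intervention"].iterrows():
            assert row["cost"] == pytest.approx(det.total_cost, abs=1e-9)
            assert row["qalys"] == pytest.approx(det.qalys, abs=1e-12)

    def test_probability_dominant_matches_analytic_tail(self):
        """With only the comparator's drug price sampled, the cost difference is
        normal with known moments, so P(dominant) has a closed form."""
        ps = make_toy_ps(horizon_years=2, comparator_extra_injections=4.0,
                         drug_cost=100.0, injection_disutility=0.001)
        sigma = 30.0
        spec = PSASpec(entries=[PSAEntry("treatments[1].drug_cost_per_injection",
                                         "normal", {"mu": 100.0, "sigma": sigma})],
                       n_draws=400, seed=21)
        base_int = evaluate(ps, "intervention")
        base_cmp = evaluate(ps, "comparator")
        # comparator cost is linear in its drug price: slope = discounted injections
        slope = base_cmp.drug_cost / 100.0
        mean_delta = base_cmp.total_cost - base_int.total_cost
        p_analytic = stats.norm.sf(0.0, loc=mean_delta, scale=sigma * slope)
        res = run_psa(ps, spec)
        p_hat = res.p_dominant["comparator"]
        se = np.sqrt(p_analytic * (1 - p_analytic) / 400)
        assert abs(p_hat - p_analytic) < 3 * se

    def test_common_random_numbers_reduce_difference_variance(self):
        """A shared cost shock cancels under common random numbers but not under
        independently paired draws."""
        from retinaecon import BilateralInputs

        ps = make_toy_ps(horizon_years=2, comparator_extra_injections=2.0,
                         supportive_annual=1000.0,
                         baseline=(0.0, 0.0, 0.0, 0.0, 0.5, 0.5),
                         bilateral=BilateralInputs(1.0, 0.0, 0.5))
        spec = PSASpec(entries=[PSAEntry("supportive.annual_cost", "gamma",
                                         {"shape": 25.0, "scale": 40.0})],
                       n_draws=60, seed=2)
        res = run_psa(ps, spec)
        wide = res.draws.pivot(index="draw", columns="treatment", values="cost")
        paired = (wide["comparator"] - wide["intervention"]).to_numpy()
        rng = np.random.default_rng(0)
        shuffled = wide["comparator"].to_numpy() - rng.permutation(
            wide["intervention"].to_numpy())
        assert paired.var() <= shuffled.var()

    def test_nmb_identity_on_incremental_rows(self, short_ps):
        results, incs = full_cea(short_ps)
        for inc in incs:
            assert inc.nmb - (short_ps.settings.wtp_threshold * inc.delta_qaly
                              + inc.delta_cost) == pytest.approx(0.0, abs=1e-6)


class TestCEAC:
    def _draws(self, costs_a, costs_b, qalys_a, qalys_b):
        n = len(costs_a)
        return pd.DataFrame({
            "draw": list(range(n)) * 2,
            "treatment": ["A"] * n + ["B"] * n,
            "cost": list(costs_a) + list(costs_b),
            "qalys": list(qalys_a) + list(qalys_b),
        })

    def test_single_treatment_probability_one_everywhere(self):
        draws = pd.DataFrame({"draw": [0, 1], "treatment": ["A", "A"],
                              "cost": [1.0, 2.0], "qalys": [1.0, 1.1]})
        curve = ceac(draws, [0, 5988, 20000])
        assert np.allclose(curve.probabilities["A"], 1.0)

    def test_zero_wtp_prefers_cheapest(self):
        draws = self._draws([100] * 10, [200] * 10, [1.0] * 10, [2.0] * 10)
        curve = ceac(draws, [0.0])
        assert curve.probabilities.loc[0.0, "A"] == 1.0

    def test_constructed_win_fraction(self):
        """A wins exactly 448 of 1000 draws at the threshold: CEAC reads 0.448."""
        n = 1000
        costs_a = np.full(n, 100.0)
        costs_b = np.where(np.arange(n) < 448, 150.0, 50.0)  # A cheaper in 448 draws
        draws = self._draws(costs_a, costs_b, np.ones(n), np.ones(n))
        curve = ceac(draws, [5988.0])
        assert curve.probabilities.loc[5988.0, "A"] == pytest.approx(0.448)

    def test_probability_vectors_sum_to_one_with_ties_split(self):
        draws = self._draws([100, 100], [100, 200], [1.0, 1.0], [1.0, 2.0])
        curve = ceac(draws, np.linspace(0, 10000, 21))
        sums = curve.probabilities.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        # first draw ties at wtp 0: split equally
        assert curve.probabilities.loc[0.0, "A"] == pytest.approx(0.75)

    def test_infinite_wtp_limit_is_probability_of_most_qalys(self):
        rng = np.random.default_rng(8)
        qa, qb = rng.normal(5, 0.5, 200), rng.normal(5, 0.5, 200)
        draws = self._draws(rng.normal(100, 5, 200), rng.normal(100, 5, 200), qa, qb)
        curve = ceac(draws, [1e12])
        assert curve.probabilities.iloc[0]["A"] == pytest.approx((qa > qb).mean())

    def test_empty_grid_rejected(self):
        draws = self._draws([1.0], [2.0], [1.0], [1.0])
        with pytest.raises(ValueError):
            ceac(draws, [])
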